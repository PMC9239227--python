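"""OTU-level community statistics for dual-enrichment series.

Takes an OTU count table (samples x OTUs), per-sample metadata locating each
vial in the enrichment design (line, replicate, cycle, substrate), and total
16S rRNA gene copy numbers per vial from ddPCR.  Provides rarefaction,
absolute-abundance scaling, the per-enrichment net enrichment statistic

    R_i = ln( N(i) / (N(i-1) * f) ),

niche classification of OTUs from their mean R on each substrate, Ward
clustering of abundance profiles into clades, SIMPER decomposition of
between-group Bray-Curtis dissimilarity, and a thin PCA wrapper.

R_i corrects the observed change in absolute abundance for the transfer
dilution f: R_i = 0 means the OTU was merely diluted (no net growth or
death), positive values mean net growth during the enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

__all__ = [
    "SampleMeta",
    "OTUTable",
    "NicheClassification",
    "CladeMap",
    "rarefy",
    "absolute_abundance",
    "enrichment_ratio",
    "enrichment_ratio_table",
    "classify_niche",
    "cluster_clades",
    "simper",
    "doublings",
    "pca_profiles",
    "PSEUDO_ABUNDANCE",
]

#: Pseudo-abundance (16S copies per vial) substituted for a zero previous
#: abundance in R_i; below any detectable copy number.
PSEUDO_ABUNDANCE = 0.5

LINES = ("D", "SD")
SUBSTRATES = ("digestate", "soil", "inoculum", "sterile_control")


@dataclass(frozen=True)
class SampleMeta:
    """Coordinates of one sample in the dual-enrichment design."""

    sample_id: str
    line: str
    replicate: str
    cycle: int
    substrate: str

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if self.cycle == 0 and self.substrate not in ("inoculum", "sterile_control"):
            raise ValueError("cycle 0 must be an inoculum or sterile-control sample")


@dataclass
class OTUTable:
    """Integer OTU counts, samples as rows and OTUs as columns."""

    counts: pd.DataFrame
    meta: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if not np.issubdtype(c.dtype, np.integer) or np.any(c < 0):
            raise ValueError("counts must be non-negative integers")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("sample and OTU ids must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative(self) -> pd.DataFrame:
        """Relative abundances; rows sum to 1."""
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)


@dataclass
class NicheClassification:
    """Per-OTU mean enrichment ratios and the derived niche category."""

    table: pd.DataFrame  # columns: R_soil_mean, R_digestate_mean, category

    def census(self) -> pd.Series:
        return self.table["category"].value_counts()


@dataclass
class CladeMap:
    """Clade label per clustered OTU plus the linkage matrix behind it."""

    clades: pd.Series          # otu_id -> clade letter
    linkage_matrix: np.ndarray
    otu_order: list[str]

    def members(self, clade: str) -> list[str]:
        return list(self.clades.index[self.clades == clade])


def rarefy(
    table: OTUTable, depth: int = 9000, seed: int | None = 0
) -> tuple[OTUTable, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads cannot be rarefied and are
    dropped; their ids are returned alongside the rarefied table.  Seeded
    and reproducible.  A sample with exactly ``depth`` reads is returned
    unchanged.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    kept_rows = {}
    dropped: list[str] = []
    for sid, row in table.counts.iterrows():
        counts = row.to_numpy(dtype=np.int64)
        total = int(counts.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            kept_rows[sid] = counts
        else:
            kept_rows[sid] = rng.multivariate_hypergeometric(counts, depth)
    rarefied = pd.DataFrame.from_dict(
        kept_rows, orient="index", columns=table.counts.columns, dtype=np.int64
    )
    meta = {sid: m for sid, m in table.meta.items() if sid in kept_rows}
    return OTUTable(counts=rarefied, meta=meta), dropped


def absolute_abundance(
    table: OTUTable, total_copies: Mapping[str, float]
) -> pd.DataFrame:
    """Scale relative abundances by ddPCR totals to 16S copies per vial.

    ``abs[s, k] = count[s, k] / sum_k count[s, k] * total_copies[s]``; row
    sums equal the ddPCR totals exactly.
    """
    missing = [s for s in table.sample_ids if s not in total_copies]
    if missing:
        raise ValueError(f"samples missing from ddPCR totals: {missing}")
    bad = [s for s in table.sample_ids if not total_copies[s] > 0]
    if bad:
        raise ValueError(f"ddPCR totals must be > 0; offending samples: {bad}")
    totals = pd.Series({s: float(total_copies[s]) for s in table.sample_ids})
    return table.relative().mul(totals, axis=0)


def enrichment_ratio(n_curr, n_prev, f: float = 0.1):
    """``R_i = ln(N(i) / (N(i-1) * f))`` with pseudo-abundance handling.

    Zero abundances are replaced by :data:`PSEUDO_ABUNDANCE`; if both are
    zero the ratio is undefined and NaN is returned (flagged).  Accepts
    scalars or arrays.
    """
    if not (0 < f <= 1):
        raise ValueError("transfer fraction must be in (0, 1]")
    n_curr = np.asarray(n_curr, dtype=float)
    n_prev = np.asarray(n_prev, dtype=float)
    both_zero = (n_curr == 0) & (n_prev == 0)
    prev = np.where(n_prev > 0, n_prev, PSEUDO_ABUNDANCE)
    curr = np.where(n_curr > 0, n_curr, PSEUDO_ABUNDANCE)
    with np.errstate(divide="ignore"):
        r = np.log(curr / (prev * f))
    r = np.where(both_zero, np.nan, r)
    return float(r) if r.ndim == 0 else r


def enrichment_ratio_table(
    abundance: pd.DataFrame,
    meta: Mapping[str, SampleMeta],
    f: float = 0.1,
) -> pd.DataFrame:
    """Per-OTU R_i for every consecutive enrichment within each line and
    replicate.

    ``abundance`` holds absolute abundances (copies per vial), samples as
    rows.  Returns a long-format frame with columns line, replicate, cycle,
    substrate, otu_id, R.  The substrate attributed to R_i is that of the
    enrichment being evaluated (cycle i); pairs separated by a dropped
    sample are skipped.
    """
    rows = []
    by_coord: dict[tuple[str, str], dict[int, SampleMeta]] = {}
    for sid, m in meta.items():
        if sid not in abundance.index:
            continue
        by_coord.setdefault((m.line, m.replicate), {})[m.cycle] = m
    for (line, rep), cycles in sorted(by_coord.items()):
        order = sorted(cycles)
        for prev_c, curr_c in zip(order[:-1], order[1:]):
            if curr_c != prev_c + 1:
                continue
            m = cycles[curr_c]
            if m.substrate not in ("soil", "digestate"):
                continue
            n_prev = abundance.loc[cycles[prev_c].sample_id].to_numpy(dtype=float)
            n_curr = abundance.loc[m.sample_id].to_numpy(dtype=float)
            r = enrichment_ratio(n_curr, n_prev, f)
            rows.append(
                pd.DataFrame(
                    {
                        "line": line,
                        "replicate": rep,
                        "cycle": curr_c,
                        "substrate": m.substrate,
                        "otu_id": abundance.columns,
                        "R": r,
                    }
                )
            )
    if not rows:
        raise ValueError("no consecutive enrichment pairs found in metadata")
    return pd.concat(rows, ignore_index=True)


def classify_niche(
    r_table: pd.DataFrame,
    threshold_high: float = 2.0,
    threshold_low: float = 0.0,
) -> NicheClassification:
    """Assign each OTU a niche category from its mean R per substrate.

    Means are taken per line x replicate over that replicate's enrichments
    in the substrate, then averaged across replicates.  Categories:

    - generalist: R_soil and R_digestate both > ``threshold_high``
    - soil_specialist: R_soil > high and R_digestate <= ``threshold_low``
    - digestate_specialist: symmetric
    - washout: everything else
    """
    per_rep = (
        r_table.groupby(["otu_id", "substrate", "line", "replicate"], sort=False)["R"]
        .mean()
        .groupby(["otu_id", "substrate"])
        .mean()
        .unstack("substrate")
    )
    rs = per_rep.get("soil")
    rd = per_rep.get("digestate")
    if rs is None or rd is None:
        raise ValueError("need R values for both soil and digestate enrichments")
    cat = pd.Series("washout", index=per_rep.index, name="category")
    cat[(rs > threshold_high) & (rd > threshold_high)] = "generalist"
    cat[(rs > threshold_high) & (rd <= threshold_low)] = "soil_specialist"
    cat[(rd > threshold_high) & (rs <= threshold_low)] = "digestate_specialist"
    out = pd.DataFrame({"R_soil_mean": rs, "R_digestate_mean": rd, "category": cat})
    return NicheClassification(table=out)


def cluster_clades(
    relative: pd.DataFrame,
    top_n: int = 500,
    n_clades: int = 6,
) -> CladeMap:
    """Ward clustering of OTU abundance profiles into clades.

    Selects the ``top_n`` OTUs by abundance summed across all samples,
    clusters their profiles (OTUs as items, samples as features) with
    Euclidean distance and Ward linkage, and cuts the tree into
    ``n_clades`` flat clusters, labelled A, B, ... in order of first
    appearance along the OTU list.
    """
    if top_n > relative.shape[1]:
        raise ValueError(f"top_n={top_n} exceeds the {relative.shape[1]} available OTUs")
    if n_clades > top_n:
        raise ValueError("n_clades cannot exceed top_n")
    top = relative.sum(axis=0).sort_values(ascending=False).index[:top_n]
    profiles = relative[top].T.to_numpy(dtype=float)
    Z = linkage(profiles, method="ward", metric="euclidean")
    flat = fcluster(Z, t=n_clades, criterion="maxclust")
    letters: dict[int, str] = {}
    labels = []
    for c in flat:
        if c not in letters:
            letters[c] = chr(ord("A") + len(letters))
        labels.append(letters[c])
    clades = pd.Series(labels, index=pd.Index(top, name="otu_id"), name="clade")
    return CladeMap(clades=clades, linkage_matrix=Z, otu_order=list(top))


def simper(
    relative: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """SIMPER: per-OTU contribution to mean between-group Bray-Curtis
    dissimilarity.

    For every cross-group sample pair (i, j) the per-OTU Bray-Curtis term is
    ``delta_k = |x_ik - x_jk| / sum_m (x_im + x_jm)``; the OTU contribution
    is its mean over pairs, expressed both in dissimilarity units and as a
    percentage of the mean overall dissimilarity (contributions sum to
    100%).

    Raises ValueError for an empty group; if the groups are identical
    (overall dissimilarity 0) percentage contributions are undefined (NaN).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    xa = relative.loc[group_a].to_numpy(dtype=float)
    xb = relative.loc[group_b].to_numpy(dtype=float)
    # all cross-group pairs at once: a-samples x b-samples x otus
    diff = np.abs(xa[:, None, :] - xb[None, :, :])
    denom = (xa.sum(axis=1)[:, None] + xb.sum(axis=1)[None, :])[:, :, None]
    delta = diff / denom
    contrib = delta.mean(axis=(0, 1))
    overall = contrib.sum()
    if overall <= 0:
        pct = np.full_like(contrib, np.nan)
    else:
        pct = 100.0 * contrib / overall
    out = pd.DataFrame(
        {"contribution": contrib, "percent": pct},
        index=pd.Index(relative.columns, name="otu_id"),
    )
    out.attrs["mean_dissimilarity"] = float(overall)
    return out.sort_values("contribution", ascending=False)


def doublings(r_sum: float) -> float:
    """Cell divisions equivalent to a summed enrichment ratio:
    ``R_sum / ln 2``."""
    return float(r_sum) / float(np.log(2.0))


def pca_profiles(relative: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """PCA of sample community profiles (thin wrapper over scikit-learn).

    Returns sample scores; explained variance ratios and total variance are
    attached in ``attrs``.
    """
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(relative.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    out = pd.DataFrame(scores, index=relative.index, columns=cols)
    out.attrs["explained_variance_ratio"] = model.explained_variance_ratio_
    out.attrs["total_variance"] = float(model.explained_variance_.sum())
    return out
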