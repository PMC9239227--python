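"""Pipeline configuration and end-to-end orchestration.

A pipeline run chains: regime mapping of the competition model, synthetic
(or user-supplied) community data through the community statistics, and a
synthetic gas incubation through the gas calculus.  Configuration is a JSON
document with one optional block per stage; every default is serialized
into the output bundle for provenance.  Validation is fail-fast: a broken
config (missing input file, inconsistent stage wiring) raises before any
stage writes output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from dualenrich import community as cm
from dualenrich import competition as cp
from dualenrich import gas as gk
from dualenrich import io as dio
from dualenrich import synth

log = logging.getLogger("dualenrich")

STAGES = ("regime", "community", "gas")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    regime: dict[str, Any] = field(default_factory=dict)
    community: dict[str, Any] = field(default_factory=dict)
    gas: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    verbosity: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if k == "stages" else v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; known: {list(STAGES)}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"configured input {key!r} not found: {path}")
        if "community" in self.stages and self.inputs:
            need = {"counts", "meta", "ddpcr"}
            have = set(self.inputs)
            if have & need and not need <= have:
                raise ValueError(
                    f"community stage with file inputs needs all of {sorted(need)}; "
                    f"got {sorted(have & need)}"
                )
        # instantiating the specs validates the parameter blocks
        synth.CommunitySpec(**{"seed": self.seed, **self.community})
        gas_kwargs = dict(self.gas)
        pops = gas_kwargs.pop("populations", None)
        if pops is not None:
            gas_kwargs["populations"] = tuple(synth.GasPopulation(*p) for p in pops)
        synth.GasSimSpec(**{"seed": self.seed, **gas_kwargs})


def _run_regime(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    block = dict(cfg.regime)
    ratio = float(block.get("ratio", 0.5))
    deficit = float(block.get("initial_deficit", 1e-4))
    n_passages = int(block.get("n_passages", 7))
    proto, traits = cp.default_protocol(ratio=ratio, initial_deficit=deficit, n_passages=n_passages)
    passages = cp.passages_to_dominance(proto, traits, "generalist")
    proto1, traits1 = cp.default_protocol(n_passages=1)
    crit = cp.critical_ratio(proto1, traits1, 0.1, 0.5, tol=0.005)
    traj = cp.run_transfer_series(proto, traits)
    dio.write_trajectory(traj, out / "trajectory.tsv")
    return {
        "generalist_ratio": ratio,
        "passages_to_dominance": passages,
        "critical_ratio_percent": round(100.0 * crit),
    }


def _run_community(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    if cfg.inputs:
        table = dio.read_counts(cfg.inputs["counts"], dio.read_meta(cfg.inputs["meta"]))
        totals = dio.read_ddpcr(cfg.inputs["ddpcr"])
        meta = table.meta
        f = float(cfg.community.get("transfer_fraction", 0.1))
        depth = int(cfg.community.get("sequencing_depth", 9000))
    else:
        spec = synth.CommunitySpec(**{"seed": cfg.seed, **cfg.community})
        ds = synth.generate_enrichment_dataset(spec)
        table, meta, totals = ds.table, ds.meta, ds.ddpcr_totals
        dio.write_counts(table, out / "otu_counts.tsv")
        dio.write_meta(meta, out / "sample_meta.tsv")
        dio.write_ddpcr(totals, out / "ddpcr.tsv")
        ds.truth.to_csv(out / "truth_labels.tsv", sep="\t")
        f, depth = spec.transfer_fraction, spec.sequencing_depth

    rarefied, dropped = cm.rarefy(table, depth=depth, seed=cfg.seed)
    abundance = cm.absolute_abundance(rarefied, totals)
    r_table = cm.enrichment_ratio_table(abundance, meta, f=f)
    niches = cm.classify_niche(
        r_table,
        threshold_high=float(cfg.community.get("threshold_high", 2.0)),
        threshold_low=float(cfg.community.get("threshold_low", 0.0)),
    )
    n_otus = rarefied.counts.shape[1]
    clades = cm.cluster_clades(
        rarefied.relative(),
        top_n=min(500, n_otus),
        n_clades=int(cfg.community.get("n_clades", 6)),
    )
    r_table.to_csv(out / "enrichment_ratios.tsv", sep="\t", index=False)
    niches.table.to_csv(out / "niche_classification.tsv", sep="\t")
    clades.clades.to_csv(out / "clades.tsv", sep="\t")
    return {
        "n_samples": len(rarefied.sample_ids),
        "dropped_samples": dropped,
        "niche_census": {k: int(v) for k, v in niches.census().items()},
        "clade_sizes": {k: int(v) for k, v in clades.clades.value_counts().items()},
    }


def _run_gas(cfg: PipelineConfig, out: Path) -> dict[str, Any]:
    gas_kwargs = dict(cfg.gas)
    pops = gas_kwargs.pop("populations", None)
    if pops is not None:
        gas_kwargs["populations"] = tuple(synth.GasPopulation(*p) for p in pops)
    spec = synth.GasSimSpec(**{"seed": cfg.seed, **gas_kwargs})
    raw, _true = synth.generate_gas_series(spec)
    corrected = gk.correct_series(raw, spec.vial)
    dio.write_gas_series(raw, out / "gas_raw.tsv")
    corrected.cumulative.to_csv(out / "gas_cumulative.tsv", sep="\t")
    corrected.rates.to_csv(out / "gas_rates.tsv", sep="\t")

    summary: dict[str, Any] = {
        "cumulative_N2_umol_N": float(corrected.cumulative["N2"].iloc[-1]),
    }
    rates = corrected.rates["N2"]
    anoxic = corrected.rates["O2"] >= -1e-9  # intervals without O2 respiration
    pos = rates[anoxic & (rates > 0)]
    if len(pos) > 1:
        pos = pos.iloc[1:]  # drop the oxic/anoxic transition interval
    if len(pos) >= 8:
        try:
            fit = gk.two_population_fit(pos.index.to_numpy(), pos.to_numpy())
            summary["two_population_fit"] = {
                "rate_decline_per_h": fit.rate_decline,
                "rate_growth_per_h": fit.rate_growth,
            }
        except RuntimeError as exc:
            summary["two_population_fit"] = {"error": str(exc)}
    # transfer to a follow-up enrichment, emulating the stable-rate regime of
    # later cycles: the next vial starts at the previous end activity scaled
    # by the transfer fraction and a planted survival level
    survival = float(cfg.gas.get("true_survival", 0.8))
    f = float(cfg.gas.get("transfer_fraction", 0.1))
    end_activity = sum(
        p.initial_rate * np.exp(p.exponent * spec.duration) for p in spec.populations
    )
    pair = []
    for rate in (end_activity, survival * f * end_activity):
        s = synth.GasSimSpec(
            populations=(synth.GasPopulation(rate, 0.0),),
            o2_dose=0.0,
            noise_cv=spec.noise_cv,
            seed=spec.seed + 1,
            vial=spec.vial,
            duration=24.0,
            sample_interval=spec.sample_interval,
        )
        raw_i, _ = synth.generate_gas_series(s)
        pair.append(gk.correct_series(raw_i, spec.vial))
    _, prev_end = gk.initial_and_end_rates(pair[0])
    next_init, _ = gk.initial_and_end_rates(pair[1])
    summary["survival_fraction_percent"] = gk.survival_fraction(prev_end, next_init, f=f)
    return summary


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the configured stages in order and write ``summary.json``.

    Raises on the first stage failure (the stage is named in the log);
    config errors surface before any output is written.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))
    summary: dict[str, Any] = {
        "config": {
            "seed": cfg.seed,
            "stages": list(cfg.stages),
            "regime": cfg.regime,
            "community": cfg.community,
            "gas": cfg.gas,
        }
    }
    runners = {"regime": _run_regime, "community": _run_community, "gas": _run_gas}
    for stage in cfg.stages:
        log.info("running stage %s", stage)
        try:
            summary[stage] = runners[stage](cfg, out)
        except Exception:
            log.error("stage %s failed", stage)
            raise
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
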