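"""Tab-separated readers and writers for the pipeline's on-disk formats.

Formats (all plain TSV):

* trajectory: ``time_h``, ``enrichment_index``, ``substrate``, then one
  column per species (biomass units).
* gas series (long): ``time_h``, ``gas``, ``amount_umol``, ``sampled``
  (0/1), ``injected_umol``; one row per (time, gas).
* OTU counts: OTUs as rows, samples as columns, integer counts.
* sample metadata: ``sample_id``, ``line``, ``replicate``, ``cycle``,
  ``substrate``.
* ddPCR totals: ``sample_id``, ``copies_per_vial``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from dualenrich.community import OTUTable, SampleMeta
from dualenrich.competition import SpeciesTraits, SubstrateEnv, TransferProtocol, Trajectory
from dualenrich.gas import GasSeries, VialSpec


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    enrich_idx = np.zeros(traj.times.size, dtype=int)
    for i, b in enumerate(traj.enrichment_boundaries):
        enrich_idx[b:] = i
    df = pd.DataFrame({"time_h": traj.times, "enrichment_index": enrich_idx})
    df["substrate"] = [traj.substrates[i] for i in enrich_idx]
    for k, name in enumerate(traj.species):
        df[name] = traj.abundances[k]
    df.to_csv(path, sep="\t", index=False)


def write_gas_series(series: GasSeries, path: str | Path) -> None:
    inj: dict[tuple[float, str], float] = {}
    for t, g, a in series.injections:
        inj[(t, g)] = inj.get((t, g), 0.0) + a
    rows = []
    for k, t in enumerate(series.times):
        for g in series.gases:
            rows.append(
                {
                    "time_h": t,
                    "gas": g,
                    "amount_umol": series.amounts.iloc[k][g],
                    "sampled": int(series.sampled[k]),
                    "injected_umol": inj.get((t, g), 0.0),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gas_series(path: str | Path) -> GasSeries:
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot(index="time_h", columns="gas", values="amount_umol").sort_index()
    sampled = (
        df.groupby("time_h")["sampled"].max().sort_index().to_numpy(dtype=bool)
    )
    injections = [
        (row.time_h, row.gas, row.injected_umol)
        for row in df.itertuples()
        if row.injected_umol > 0
    ]
    wide.columns.name = None
    return GasSeries(amounts=wide, sampled=sampled, injections=injections)


def read_vial(path: str | Path) -> VialSpec:
    with open(path) as fh:
        return VialSpec(**json.load(fh))


def write_counts(table: OTUTable, path: str | Path) -> None:
    # OTUs as rows, samples as columns
    table.counts.T.rename_axis("otu_id").to_csv(path, sep="\t")


def read_counts(path: str | Path, meta: Mapping[str, SampleMeta] | None = None) -> OTUTable:
    df = pd.read_csv(path, sep="\t", index_col=0).T
    df.index.name = "sample_id"
    return OTUTable(counts=df.astype(np.int64), meta=dict(meta) if meta else {})


def write_meta(meta: Mapping[str, SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "line": m.line,
            "replicate": m.replicate,
            "cycle": m.cycle,
            "substrate": m.substrate,
        }
        for m in meta.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_meta(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.sample_id: SampleMeta(
            sample_id=row.sample_id,
            line=row.line,
            replicate=row.replicate,
            cycle=int(row.cycle),
            substrate=row.substrate,
        )
        for row in df.itertuples()
    }


def write_ddpcr(totals: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(totals), "copies_per_vial": list(totals.values())}
    ).to_csv(path, sep="\t", index=False)


def read_ddpcr(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"], df["copies_per_vial"].astype(float)))


def read_model_config(path: str | Path) -> tuple[TransferProtocol, list[SpeciesTraits]]:
    """Competition-model config JSON: substrate sequence with capacities and
    durations, transfer fraction, passage count, traits and inoculum."""
    with open(path) as fh:
        cfg = json.load(fh)
    envs = [
        SubstrateEnv(e["substrate_id"], e["carrying_capacity"], e["duration"])
        for e in cfg["substrate_sequence"]
    ]
    traits = [
        SpeciesTraits(t["name"], t["growth_rate"], t["death_rate"])
        for t in cfg["traits"]
    ]
    protocol = TransferProtocol(
        substrate_sequence=envs,
        transfer_fraction=cfg.get("transfer_fraction", 0.1),
        n_passages=cfg.get("n_passages", 7),
        initial_abundance=cfg["initial_abundance"],
    )
    return protocol, traits
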