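"""End-to-end pipeline driver and tabular outputs.

Ties the stages together: input (counts table, parsed chains, or the
synthetic generator) → per-bin counts → potential table (raw and
reference-corrected) → between-bin differences with resampling
p-values and split-sample errors → weighted parabola fits → TSV files
plus a JSON run manifest. All randomness flows from the single seed in
the run configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amino_acids import AMINO_ACIDS, CLASSES, REFERENCE_TYPES, resolve_entity
from .errors import HydrotempError, TooFewChains
from . import inference, potentials, synthetic
from .ingest import ChainCounts, read_counts_table, write_counts_table
from .inference import (
    BIN_LOW,
    BIN_ROOM,
    TEMPERATURE_BINS,
    bin_chains,
    bin_mean_temperatures,
    make_bin_estimator,
    resample_pvalue,
    split_standard_error,
)
from .potentials import chain_to_counts, compute_potential_table, aggregate_bin_counts

#: Cells whose significance is resampled by default: pooled classes on
#: the raw scale, individual hydrophobic/aromatic/other residues on the
#: reference-corrected scale.
DEFAULT_SIGNIFICANCE_ENTITIES: tuple[tuple[str, bool], ...] = tuple(
    [(cls, False) for cls in CLASSES]
    + [
        (aa, True)
        for aa in sorted(
            CLASSES["hydrophobic"] + CLASSES["aromatic"] + CLASSES["other"]
        )
    ]
)

DEFAULT_CONFIG: dict = {
    "burial_cutoff": potentials.DEFAULT_BURIAL_CUTOFF,
    "q": potentials.DEFAULT_Q,
    "n_resamples": 1000,
    "seed": 0,
    "reference_classes": ["charged", "polar"],
    "methods": ["contact", "surface", "area", "scaled_area"],
    "significance_methods": ["contact", "surface"],
    "max_asa_table": None,  # None -> built-in theoretical scale
}


def _reference_types(config: Mapping) -> tuple[str, ...]:
    classes = config.get("reference_classes") or ["charged", "polar"]
    types: list[str] = []
    for cls in classes:
        types.extend(resolve_entity(cls))
    return tuple(types)


@dataclass
class RunManifest:
    config: dict
    input_paths: dict
    seed: int
    stage_rows: dict = field(default_factory=dict)
    output_paths: dict = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def temperature_histogram(chains: Sequence) -> pd.DataFrame:
    """Integer-kelvin histogram of chain temperatures, bins annotated."""
    temps = [int(np.floor(c.temperature + 0.5)) for c in chains]
    counts: dict[int, int] = {}
    for t in temps:
        counts[t] = counts.get(t, 0) + 1
    rows = [
        (t, counts[t], inference.assign_bin(float(t)) or "")
        for t in sorted(counts)
    ]
    return pd.DataFrame(rows, columns=["temperature_K", "count", "bin"])


def _load_chains(inputs: Mapping, seed: int) -> tuple[list, dict]:
    paths = {}
    if "counts_table" in inputs:
        path = Path(inputs["counts_table"])
        if not path.exists():
            raise HydrotempError(f"counts table not found: {path}")
        paths["counts_table"] = str(path)
        return list(read_counts_table(path)), paths
    if "chains" in inputs:
        return list(inputs["chains"]), paths
    if "synthetic" in inputs:
        cfg = inputs["synthetic"]
        if not isinstance(cfg, synthetic.GeneratorConfig):
            cfg = synthetic.GeneratorConfig(**(cfg or {}))
        return synthetic.sample_dataset(cfg, seed=seed), paths
    raise HydrotempError(
        "inputs must provide one of: counts_table, chains, synthetic"
    )


def significance_table(
    groups: Mapping[str, Sequence],
    config: Mapping,
    entities: Sequence[tuple[str, bool]] = DEFAULT_SIGNIFICANCE_ENTITIES,
) -> pd.DataFrame:
    """ΔΔG (room − low), split-sample SE, and resampling p per cell."""
    cfg = {**DEFAULT_CONFIG, **config}
    seed = int(cfg["seed"])
    ref_types = _reference_types(cfg)
    low = groups.get(BIN_LOW, [])
    room = groups.get(BIN_ROOM, [])
    rows = []
    for method in cfg["significance_methods"]:
        for entity, corrected in entities:
            try:
                sig = resample_pvalue(
                    low, room, entity, method,
                    corrected=corrected,
                    n_resamples=int(cfg["n_resamples"]),
                    seed=seed,
                    burial_cutoff=cfg["burial_cutoff"],
                    q=cfg["q"],
                    reference_types=ref_types,
                    max_asa=cfg["max_asa_table"],
                )
            except HydrotempError:
                continue
            estimator = make_bin_estimator(
                entity, method, corrected=corrected,
                burial_cutoff=cfg["burial_cutoff"], q=cfg["q"],
                reference_types=ref_types, max_asa=cfg["max_asa_table"],
            )
            try:
                se_low = split_standard_error(low, estimator, seed=seed).se
                se_room = split_standard_error(room, estimator, seed=seed + 1).se
                ddg_se = float(np.hypot(se_low, se_room))
            except (TooFewChains, HydrotempError):
                ddg_se = float("nan")
            rows.append((
                entity, method, corrected, sig.observed_ddg, ddg_se,
                sig.p_value, sig.formatted_p(), sig.n_resamples,
            ))
    return pd.DataFrame(rows, columns=[
        "entity", "method", "corrected", "ddG_kT", "ddG_se_kT",
        "p_value", "p_display", "n_resamples",
    ])


def fit_table(
    table: pd.DataFrame,
    bin_counts: Mapping[str, potentials.BinCounts],
    entities: Sequence[str],
    methods: Sequence[str],
) -> pd.DataFrame:
    """Weighted parabola fits per (entity, method, corrected).

    Weights are the entity's residue counts per bin, matching the
    fitting weights used for the published curves.
    """
    from .amino_acids import AA_INDEX

    rows = []
    for corrected in (False, True):
        for method in methods:
            for entity in entities:
                pts, wts = [], []
                for bin_id, counts in bin_counts.items():
                    val = potentials.get_cell(table, bin_id, entity, method, corrected)
                    t_mean = float(
                        table.loc[table["bin"] == bin_id, "temperature_mean"].iloc[0]
                    )
                    idx = [AA_INDEX[t] for t in resolve_entity(entity)]
                    pts.append((t_mean, val))
                    wts.append(float(counts.n[idx].sum()))
                try:
                    fit = inference.fit_parabola(pts, wts)
                except HydrotempError:
                    continue
                rows.append((
                    entity, method, corrected, fit.a2, fit.a1, fit.a0,
                    fit.vertex_temperature, fit.is_maximum,
                    fit.weighted_residual_sum,
                ))
    return pd.DataFrame(rows, columns=[
        "entity", "method", "corrected", "a2", "a1", "a0",
        "vertex_K", "is_maximum", "S",
    ])


def run_pipeline(config: Mapping, inputs: Mapping, outdir) -> RunManifest:
    """Run every stage and write all output tables under ``outdir``.

    ``inputs`` selects the source: ``{"counts_table": path}``,
    ``{"chains": [...]}``, or ``{"synthetic": GeneratorConfig | dict}``.
    Idempotent for a fixed seed.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    seed = int(cfg["seed"])
    outdir = Path(outdir)

    chains, input_paths = _load_chains(inputs, seed)
    manifest = RunManifest(
        config={k: v for k, v in cfg.items() if k != "max_asa_table"},
        input_paths=input_paths,
        seed=seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.stage_rows["chains"] = len(chains)

    outdir.mkdir(parents=True, exist_ok=True)

    groups = bin_chains(chains)
    mean_t = bin_mean_temperatures(groups)
    manifest.stage_rows["chains_in_bins"] = sum(len(g) for g in groups.values())

    bin_counts = {
        bin_id: aggregate_bin_counts(
            g, bin_id=bin_id, burial_cutoff=cfg["burial_cutoff"], q=cfg["q"]
        )
        for bin_id, g in groups.items()
    }

    entities = tuple(CLASSES) + AMINO_ACIDS
    ref_types = _reference_types(cfg)
    table = compute_potential_table(
        bin_counts, mean_t, entities,
        methods=cfg["methods"],
        include_corrected=True,
        reference_types=ref_types,
        max_asa=cfg["max_asa_table"],
    )
    pot_path = outdir / "potentials.tsv"
    potentials.write_potential_table(table, pot_path)
    manifest.output_paths["potentials"] = str(pot_path)
    manifest.stage_rows["potential_cells"] = len(table)

    hist = temperature_histogram(chains)
    hist_path = outdir / "temperature_histogram.tsv"
    hist.to_csv(hist_path, sep="\t", index=False)
    manifest.output_paths["temperature_histogram"] = str(hist_path)

    sig = significance_table(groups, cfg)
    sig_path = outdir / "ddg_significance.tsv"
    sig.to_csv(sig_path, sep="\t", index=False, float_format="%.10g")
    manifest.output_paths["ddg_significance"] = str(sig_path)
    manifest.stage_rows["significance_cells"] = len(sig)

    fits = fit_table(table, bin_counts, entities, cfg["significance_methods"])
    fit_path = outdir / "parabola_fits.tsv"
    fits.to_csv(fit_path, sep="\t", index=False, float_format="%.10g")
    manifest.output_paths["parabola_fits"] = str(fit_path)
    manifest.stage_rows["fit_rows"] = len(fits)

    if "synthetic" in inputs:
        counts_path = outdir / "synthetic_counts.tsv"
        write_counts_table(
            [chain_to_counts(c, cfg["burial_cutoff"]) for c in chains], counts_path
        )
        manifest.output_paths["synthetic_counts"] = str(counts_path)

    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    manifest.output_paths["manifest"] = str(manifest_path)
    return manifest
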