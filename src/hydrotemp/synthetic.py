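"""Synthetic chain datasets with known temperature-dependent burial.

Each residue type belongs to a class whose transfer energy follows a
configurable downward parabola in temperature,

    g_c(T) = g_max - kappa * (T - T_peak)**2   [kT],

and exposure fractions are drawn from a Beta law whose mean is the
logistic map mu = 1 / (1 + exp(g)): a higher transfer cost means a more
buried residue. Because :func:`truth_report` evaluates the same link in
closed form, pipeline estimates can be checked against exact expected
values, and a null generator (kappa = 0 everywhere) gives datasets with
no temperature effect at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .amino_acids import (
    AA_INDEX,
    AMINO_ACIDS,
    CLASSES,
    MAX_ASA_THEORETICAL,
    REFERENCE_TYPES,
)
from .errors import InvalidConfig
from .ingest import ChainRecord, ResidueExposure
from .inference import TEMPERATURE_BINS
from .potentials import DEFAULT_BURIAL_CUTOFF, TABLE_COLUMNS

#: Approximate Swiss-Prot residue frequencies, renormalised.
DEFAULT_COMPOSITION: dict[str, float] = {
    "ALA": 0.083, "ARG": 0.055, "ASN": 0.041, "ASP": 0.055, "CYS": 0.014,
    "GLN": 0.039, "GLU": 0.067, "GLY": 0.071, "HIS": 0.023, "ILE": 0.059,
    "LEU": 0.097, "LYS": 0.058, "MET": 0.024, "PHE": 0.039, "PRO": 0.047,
    "SER": 0.066, "THR": 0.054, "TRP": 0.011, "TYR": 0.029, "VAL": 0.069,
}
_total = sum(DEFAULT_COMPOSITION.values())
DEFAULT_COMPOSITION = {a: v / _total for a, v in DEFAULT_COMPOSITION.items()}

#: Default bin occupancy fractions, proportional to the filtered chain
#: counts of the real dataset (207/344/1033/560/412).
DEFAULT_OCCUPANCY: dict[str, float] = {
    "265-290": 207 / 2556,
    "291-296": 344 / 2556,
    "297-299": 1033 / 2556,
    "300-305": 560 / 2556,
    "306-340": 412 / 2556,
}


@dataclass(frozen=True)
class Curve:
    """Parabolic transfer-energy curve g(T) = g_max - kappa (T - T_peak)^2."""

    g_max: float
    kappa: float = 0.0
    t_peak: float = 320.0

    def __call__(self, temperature: float) -> float:
        dt = temperature - self.t_peak
        return self.g_max - self.kappa * dt * dt


DEFAULT_CLASS_CURVES: dict[str, Curve] = {
    "hydrophobic": Curve(g_max=0.8, kappa=4.0e-4, t_peak=315.0),
    "aromatic": Curve(g_max=0.8),
    "charged": Curve(g_max=-1.0),
    "polar": Curve(g_max=-0.6),
    "other": Curve(g_max=0.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_chains: int = 1500
    length_mean: float = 100.0
    length_sd: float = 30.0
    min_length: int = 20
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    class_curves: Mapping[str, Curve] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CURVES)
    )
    #: optional per-type overrides of the class curve
    type_curves: Mapping[str, Curve] = field(default_factory=dict)
    #: Beta concentration nu; alpha ~ Beta(mu*nu, (1-mu)*nu)
    concentration: float = 2.0
    bin_occupancy: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY)
    )
    seed: int | None = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_chains <= 0:
            raise InvalidConfig("n_chains must be positive")
        if self.concentration <= 0:
            raise InvalidConfig("concentration must be positive")
        comp = np.array([self.composition.get(a, 0.0) for a in AMINO_ACIDS])
        if np.any(comp < 0) or not math.isclose(comp.sum(), 1.0, abs_tol=1e-8):
            raise InvalidConfig("composition must be non-negative and sum to 1")
        for name, curve in {**self.class_curves, **self.type_curves}.items():
            if curve.kappa < 0:
                raise InvalidConfig(f"kappa < 0 for {name}")
        known = set(CLASSES)
        if not set(self.class_curves) <= known:
            raise InvalidConfig(f"unknown classes: {set(self.class_curves) - known}")
        occ = np.array(
            [self.bin_occupancy.get(b, 0.0) for b, _, _ in TEMPERATURE_BINS]
        )
        if np.any(occ < 0) or occ.sum() <= 0:
            raise InvalidConfig("bin occupancy must be non-negative, not all zero")
        return self

    def null(self) -> "GeneratorConfig":
        """Copy with every temperature dependence removed (kappa = 0)."""
        flat = {c: replace(curve, kappa=0.0) for c, curve in self.class_curves.items()}
        flat_t = {a: replace(curve, kappa=0.0) for a, curve in self.type_curves.items()}
        return replace(self, class_curves=flat, type_curves=flat_t)


_CLASS_OF = {aa: cls for cls, members in CLASSES.items() for aa in members}


def transfer_energy(config: GeneratorConfig, aa: str, temperature: float) -> float:
    """g for one residue type at one temperature (kT units)."""
    curve = config.type_curves.get(aa)
    if curve is None:
        curve = config.class_curves.get(_CLASS_OF[aa], Curve(0.0))
    return curve(temperature)


def mean_exposure(config: GeneratorConfig, aa: str, temperature: float) -> float:
    """Logistic link: mu = 1 / (1 + exp(g))."""
    return 1.0 / (1.0 + math.exp(transfer_energy(config, aa, temperature)))


def _bin_chain_counts(config: GeneratorConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_chains over the bins."""
    occ = np.array([config.bin_occupancy.get(b, 0.0) for b, _, _ in TEMPERATURE_BINS])
    occ = occ / occ.sum()
    raw = occ * config.n_chains
    counts = np.floor(raw).astype(int)
    short = config.n_chains - counts.sum()
    for i in np.argsort(-(raw - counts))[:short]:
        counts[i] += 1
    return {b: int(c) for (b, _, _), c in zip(TEMPERATURE_BINS, counts)}


def sample_dataset(config: GeneratorConfig, seed: int | None = None) -> list[ChainRecord]:
    """Draw a dataset of chains; bit-identical for a fixed seed.

    Temperatures are integer kelvin, uniform within each bin; residue
    types are i.i.d. from the composition; exposure fractions are Beta
    draws around the logistic mean. Accessible areas are back-filled as
    ``alpha * max_asa`` so the records behave like parsed ones.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    comp = np.array([config.composition.get(a, 0.0) for a in AMINO_ACIDS])
    nu = config.concentration
    bounds = {b: (lo, hi) for b, lo, hi in TEMPERATURE_BINS}

    chains: list[ChainRecord] = []
    chain_no = 0
    for bin_id, n_bin in _bin_chain_counts(config).items():
        lo, hi = bounds[bin_id]
        for _ in range(n_bin):
            chain_no += 1
            temp = float(rng.integers(lo, hi + 1))
            mu = np.array(
                [mean_exposure(config, a, temp) for a in AMINO_ACIDS]
            )
            length = max(
                config.min_length,
                int(round(rng.normal(config.length_mean, config.length_sd))),
            )
            types = rng.choice(len(AMINO_ACIDS), size=length, p=comp)
            mu_r = mu[types]
            alphas = rng.beta(mu_r * nu, (1.0 - mu_r) * nu)
            alphas = np.clip(alphas, 0.0, 1.0)
            residues = tuple(
                ResidueExposure(
                    aa_type=AMINO_ACIDS[t],
                    per_model_area=(
                        float(a * MAX_ASA_THEORETICAL[AMINO_ACIDS[t]]),
                    ),
                    mean_area=float(a * MAX_ASA_THEORETICAL[AMINO_ACIDS[t]]),
                    exposure_fraction=float(a),
                )
                for t, a in zip(types, alphas)
            )
            chains.append(
                ChainRecord(
                    structure_id=f"SY{chain_no:04d}",
                    chain_id="A",
                    temperature=temp,
                    residues=residues,
                )
            )
    return chains


# --------------------------------------------------------------------------
# Closed-form expectations
# --------------------------------------------------------------------------

def _expected_bin_arrays(config: GeneratorConfig, lo: int, hi: int):
    """Per-type expected fractions for one bin: residue share f, mean
    exposure mu, burial probability p (Beta CDF at the cutoff).

    mu and p are averaged exactly over the uniform integer temperatures
    the sampler draws within the bin, so no Jensen gap is introduced by
    the nonlinear link."""
    nu = config.concentration
    f = np.array([config.composition.get(a, 0.0) for a in AMINO_ACIDS])
    temps = np.arange(lo, hi + 1, dtype=float)
    mu_t = np.array(
        [[mean_exposure(config, a, t) for a in AMINO_ACIDS] for t in temps]
    )  # (n_temps, 20)
    p_t = beta_dist.cdf(DEFAULT_BURIAL_CUTOFF, mu_t * nu, (1.0 - mu_t) * nu)
    return f, mu_t.mean(axis=0), p_t.mean(axis=0)


def _expected_energy(
    f: np.ndarray, mu: np.ndarray, p: np.ndarray, idx: list[int], method: str,
    q: float = 4.0,
) -> float:
    fe = f[idx]
    if method == "contact":
        alpha_bar = float(f @ mu)
        c = q * float(fe @ mu[idx])
        omega = float(fe.sum()) * q * alpha_bar / (1.0 + alpha_bar)
        return -math.log(c / omega)
    if method == "surface":
        num = float(fe @ p[idx]) / float(fe @ (1.0 - p[idx]))
        den = float(f @ p) / float(f @ (1.0 - p))
        return math.log(num / den)
    if method in ("area", "scaled_area"):
        value = -math.log((float(fe @ mu[idx]) / fe.sum()) / float(f @ mu))
        if method == "scaled_area":
            areas = np.array([MAX_ASA_THEORETICAL[AMINO_ACIDS[i]] for i in idx])
            value *= float(np.average(areas, weights=fe))
        return value
    raise ValueError(method)


def truth_report(
    config: GeneratorConfig,
    entities: Sequence[str] | None = None,
    methods: Sequence[str] = ("contact", "surface", "area", "scaled_area"),
) -> pd.DataFrame:
    """Expected transfer energies per (entity, bin, method), raw and
    reference-corrected, implied by the generator's link and noise law.

    Bin temperature is the midpoint of the integer sampling range.
    Expectations are ratios of expected counts, so they match pipeline
    estimates up to O(1/n) sampling error.
    """
    config.validate()
    if entities is None:
        entities = tuple(CLASSES) + AMINO_ACIDS
    ref_idx = [AA_INDEX[a] for a in REFERENCE_TYPES]
    rows = []
    for bin_id, lo, hi in TEMPERATURE_BINS:
        t_eff = (lo + hi) / 2.0
        f, mu, p = _expected_bin_arrays(config, lo, hi)
        for method in methods:
            ref = _expected_energy(f, mu, p, ref_idx, method)
            for entity in entities:
                members = CLASSES.get(entity, (entity,))
                idx = [AA_INDEX[a] for a in members]
                val = _expected_energy(f, mu, p, idx, method)
                rows.append((bin_id, t_eff, entity, method, False, val, float("nan")))
                rows.append((bin_id, t_eff, entity, method, True, val - ref, float("nan")))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def truth_ddg(
    config: GeneratorConfig,
    entity: str,
    method: str,
    corrected: bool = False,
    bin_low: str = "265-290",
    bin_room: str = "297-299",
) -> float:
    """Expected room-minus-low energy difference for one cell."""
    report = truth_report(config, entities=(entity,), methods=(method,))
    sub = report[report["corrected"] == corrected].set_index("bin")["dG_kT"]
    return float(sub[bin_room] - sub[bin_low])
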