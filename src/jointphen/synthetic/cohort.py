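"""Synthetic phenotype cohorts: correlated wild-type reference + mutant lines.

A Gaussian copula generates 18 correlated joint parameters per animal with
normal or log-normal marginals.  Mutant-line effects are expressed in SD
units and applied on the latent normal scale, so "a +2 SD shift" is
well-defined for skewed parameters too.  The default reference cohort is
100 wild-type animals, matching the screen's reference design.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .._util import substream
from ..screening import DEFAULT_PARAMETERS

__all__ = ["CohortSpec", "default_marginals", "default_correlation", "generate_cohort"]


def default_marginals() -> dict[str, tuple[str, float, float]]:
    """Plausible marginals for the 18 parameters of a healthy adult cohort.

    Values are (kind, mu, sigma); for ``lognormal`` the parameters are on
    the log scale.  Cartilage damage area is log-normal with a sub-percent
    median so healthy damage stays in the low single digits; the remaining
    morphometric parameters are normal with coefficients of variation
    around 10%.
    """
    per_side = {
        "Cg.V": ("normal", 2.5e-3, 2.5e-4),  # mm^3
        "Median Cg.Th": ("normal", 0.050, 0.005),  # mm
        "Max Cg.Th": ("normal", 0.090, 0.008),  # mm
        "Cg. Damage Area": ("lognormal", np.log(0.6), 0.55),  # % of plateau
        "SC BV/TV": ("normal", 0.35, 0.04),  # fraction
        "SC Tb.Th": ("normal", 0.045, 0.004),  # mm
        "SC Tb.N": ("normal", 7.0, 0.7),  # 1/mm
        "SC TMD": ("normal", 750.0, 35.0),  # mg HA/cm^3
        "SC BMC": ("normal", 140.0, 12.0),  # calibrated bin
    }
    return {
        f"{side} {p}": spec
        for side in ("MTP", "LTP")
        for p, spec in per_side.items()
    }


def default_correlation(n: int = 18) -> np.ndarray:
    """Block-structured correlation: 0.3 within a side, 0.1 across sides."""
    corr = np.full((n, n), 0.1)
    half = n // 2
    corr[:half, :half] = 0.3
    corr[half:, half:] = 0.3
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class CohortSpec:
    """One reference cohort plus mutant lines.

    ``lines`` holds (label, n_animals, effects) triples where ``effects``
    maps parameter names to shifts in SD units (unnamed parameters shift
    by zero); a full-length sequence in parameter order is also accepted.
    """

    n_reference: int = 100
    parameter_names: tuple[str, ...] = DEFAULT_PARAMETERS
    marginals: Mapping[str, tuple[str, float, float]] = dc_field(
        default_factory=default_marginals
    )
    correlation: np.ndarray | None = None
    lines: Sequence[tuple[str, int, Mapping[str, float] | Sequence[float]]] = ()
    reference_label: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference < 3:
            raise ValueError("n_reference must be >= 3")
        if self.correlation is None:
            self.correlation = default_correlation(len(self.parameter_names))
        corr = np.asarray(self.correlation, dtype=float)
        n = len(self.parameter_names)
        if corr.shape != (n, n):
            raise ValueError(f"correlation must be {n}x{n}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        lam = np.linalg.eigvalsh(corr)
        if lam[0] < -1e-8:
            raise ValueError(
                f"correlation matrix is not positive semidefinite "
                f"(smallest eigenvalue {lam[0]:.3g})"
            )
        self.correlation = corr
        missing = [p for p in self.parameter_names if p not in self.marginals]
        if missing:
            raise ValueError(f"marginals missing for parameters: {missing}")
        for label, n_animals, effects in self.lines:
            vec = self._effect_vector(effects)
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"line {label!r} has non-finite effects")
            if n_animals < 1:
                raise ValueError(f"line {label!r} needs at least one animal")

    def _effect_vector(self, effects) -> np.ndarray:
        names = self.parameter_names
        if isinstance(effects, Mapping):
            unknown = set(effects) - set(names)
            if unknown:
                raise ValueError(f"effects name unknown parameters: {sorted(unknown)}")
            return np.array([float(effects.get(p, 0.0)) for p in names])
        vec = np.asarray(effects, dtype=float)
        if vec.shape != (len(names),):
            raise ValueError("effect vector length must match the parameter count")
        return vec


def _copula_factor(corr: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD correlation matrix (eigen-based)."""
    lam, V = np.linalg.eigh(corr)
    lam = np.clip(lam, 0.0, None)
    return V * np.sqrt(lam)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort as a tidy table: line, animal_id, 18 parameter columns."""
    names = list(spec.parameter_names)
    factor = _copula_factor(spec.correlation)
    kinds = [spec.marginals[p][0] for p in names]
    mus = np.array([spec.marginals[p][1] for p in names])
    sigmas = np.array([spec.marginals[p][2] for p in names])
    for k in kinds:
        if k not in ("normal", "lognormal"):
            raise ValueError(f"unknown marginal kind {k!r}")
    is_log = np.array([k == "lognormal" for k in kinds])

    def _draw(rng: np.random.Generator, n: int, shift: np.ndarray) -> np.ndarray:
        z = rng.standard_normal((n, len(names))) @ factor.T + shift
        raw = mus + sigmas * z
        raw[:, is_log] = np.exp(raw[:, is_log])
        return raw

    frames = []
    rng_ref = substream(spec.seed, 30)
    ref = _draw(rng_ref, spec.n_reference, np.zeros(len(names)))
    frames.append(
        pd.DataFrame(ref, columns=names).assign(
            line=spec.reference_label,
            animal_id=[f"{spec.reference_label}-{i:03d}" for i in range(spec.n_reference)],
        )
    )
    for k, (label, n_animals, effects) in enumerate(spec.lines):
        rng_line = substream(spec.seed, 31, k)
        shift = spec._effect_vector(effects)
        vals = _draw(rng_line, n_animals, shift)
        frames.append(
            pd.DataFrame(vals, columns=names).assign(
                line=label,
                animal_id=[f"{label}-{i:03d}" for i in range(n_animals)],
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table[["line", "animal_id"] + names]
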