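"""Synthetic two-class cohorts with planted discriminative correlations.

Real resting-state cohorts are large external downloads; for testing the
whole pipeline end to end we instead simulate ROI time series in which a
chosen subset of region pairs is more strongly correlated in the patient
class (label 1) than in the control class (label 0).

Generation model (latent factor with between-subject heterogeneity):
for each planted pair (j, k) a subject-specific target correlation is
drawn in Fisher-z space,

    z_s = atanh(rho_class) * (1 + hetero * N(0, 1)),    rho_s = tanh(z_s),

with ``rho_class = effect`` for patients (label 1) and 0 for controls,
and both regions mix a shared standard-normal latent series u with the
weight that realises exactly that correlation on top of independent
Gaussian noise of sd ``noise_sd``:

    x_j(t) = a_s * u(t) + noise_sd * e_j(t),
    a_s = noise_sd * sqrt(|rho_s| / (1 - |rho_s|))  (signed).

When the planted pairs are disjoint, each subject's population
correlation on a planted pair equals rho_s, so the class-typical
correlation is ``effect`` versus 0 while ``hetero`` (the dispersion of
the planted coupling across patients, relative to its Fisher-z mean)
controls how strongly subjects within a class overlap — the knob that makes single features weak and feature subsets
strong, as in real cohorts.

A second, class-independent heterogeneity term emulates background
functional connectivity: every region loads on ``background_rank``
shared latent series with subject-specific Gaussian weights (sd
``background_sd``), so non-planted correlations vary across subjects
the way real connectomes do while carrying no class information.
Without it, non-planted features are near-constants and classifiers
can neither underfit nor overfit them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "default_planted_pairs",
    "generate_cohort",
    "write_cohort",
]


@dataclass
class SubjectRecord:
    """One subject: T x R ROI time series plus label and acquisition site."""

    subject_id: str
    site: str
    label: int
    timeseries: np.ndarray

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.timeseries.ndim != 2:
            raise ValueError("timeseries must be a T x R matrix")
        if self.timeseries.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.isfinite(self.timeseries)):
            raise ValueError("timeseries contains non-finite values")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-class cohort."""

    n_per_class: int
    R: int
    T: int
    planted_pairs: tuple[tuple[int, int], ...]
    effect: float
    noise_sd: float = 0.5
    hetero: float = 0.8
    background_rank: int = 5
    background_sd: float = 0.5
    seed: int = 0
    sites: tuple[str, ...] = ("site01", "site02")

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.R < 2:
            raise ValueError("need at least 2 regions")
        if self.T < 3:
            raise ValueError("need at least 3 time points")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError(f"effect must be in [0, 1], got {self.effect}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.hetero < 0:
            raise ValueError("hetero must be non-negative")
        if self.background_rank < 0 or self.background_sd < 0:
            raise ValueError("background parameters must be non-negative")
        if not self.sites:
            raise ValueError("need at least one site")
        seen = set()
        for j, k in self.planted_pairs:
            if j == k:
                raise ValueError(f"planted pair ({j},{k}) is a self-pair")
            if not (0 <= j < self.R and 0 <= k < self.R):
                raise ValueError(f"planted pair ({j},{k}) out of range for R={self.R}")
            key = (min(j, k), max(j, k))
            if key in seen:
                raise ValueError(f"duplicate planted pair {key}")
            seen.add(key)
        object.__setattr__(
            self, "planted_pairs", tuple(sorted((min(j, k), max(j, k)) for j, k in self.planted_pairs))
        )


def default_planted_pairs(R: int, n_pairs: int, seed: int = 0) -> tuple[tuple[int, int], ...]:
    """Sample ``n_pairs`` disjoint region pairs (no shared region).

    Disjoint pairs keep the planted population correlation exactly at the
    requested effect size.
    """
    if 2 * n_pairs > R:
        raise ValueError(f"cannot place {n_pairs} disjoint pairs among {R} regions")
    rng = np.random.default_rng(seed)
    regions = rng.permutation(R)[: 2 * n_pairs]
    pairs = [
        (int(min(a, b)), int(max(a, b)))
        for a, b in zip(regions[0::2], regions[1::2])
    ]
    return tuple(sorted(pairs))


_RHO_CAP = 0.999  # keep the mixing weight finite


def _mixing_weight(rho: float, noise_sd: float) -> float:
    """Signed latent weight realising population correlation ``rho``."""
    r = min(abs(rho), _RHO_CAP)
    return math.copysign(noise_sd * math.sqrt(r / (1.0 - r)), rho)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], list[tuple[int, int]]]:
    """Simulate ``2 * n_per_class`` subjects; returns (subjects, planted pairs).

    Class 1 subjects carry planted correlations dispersed around
    ``effect``; class 0 subjects around 0.  With ``hetero == 0`` and
    disjoint pairs the planted population correlation is exactly
    ``effect`` in class 1.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pairs = list(spec.planted_pairs)
    z1 = math.atanh(min(spec.effect, _RHO_CAP))
    # total non-latent variance per region: independent noise + background
    q, s_bg = spec.background_rank, spec.background_sd
    base_sd = math.sqrt(spec.noise_sd**2 + q * s_bg**2)

    subjects: list[SubjectRecord] = []
    width = len(str(2 * spec.n_per_class))
    idx = 0
    for label in (0, 1):
        z_class = z1 if label == 1 else 0.0
        for _ in range(spec.n_per_class):
            ts = rng.standard_normal((spec.T, spec.R)) * spec.noise_sd
            if s_bg > 0 and q > 0:
                # class-independent background: every region loads on a few
                # shared latents with subject-specific random weights, giving
                # all pairs realistic between-subject correlation variability
                loadings = rng.normal(0.0, s_bg, size=(q, spec.R))
                shared = rng.standard_normal((spec.T, q))
                ts = ts + shared @ loadings
            for j, k in pairs:
                # dispersion scales with the planted coupling itself, so a
                # zero effect leaves planted pairs exchangeable with the rest
                z_s = z_class * (1.0 + spec.hetero * rng.standard_normal())
                rho_s = math.tanh(z_s)
                a = _mixing_weight(rho_s, base_sd)
                u = rng.standard_normal(spec.T)
                ts[:, j] = ts[:, j] + abs(a) * u
                ts[:, k] = ts[:, k] + a * u
            site = spec.sites[idx % len(spec.sites)]
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub{idx:0{width}d}",
                    site=site,
                    label=label,
                    timeseries=ts,
                )
            )
            idx += 1
    return subjects, pairs


def write_cohort(
    subjects: Sequence[SubjectRecord], directory: str | Path, header: bool = False
) -> Path:
    """Write one time-series CSV per subject plus a phenotype table.

    Layout: ``<dir>/phenotype.csv`` with columns subject_id,site,label and
    ``<dir>/<subject_id>.csv`` with T rows x R columns (no header unless
    ``header=True``).
    """
    if len(subjects) == 0:
        raise ValueError("empty subject list")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pheno = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "site": [s.site for s in subjects],
            "label": [s.label for s in subjects],
        }
    )
    pheno.to_csv(directory / "phenotype.csv", index=False)
    for s in subjects:
        df = pd.DataFrame(s.timeseries)
        if header:
            df.columns = [f"region{j}" for j in range(s.timeseries.shape[1])]
        df.to_csv(directory / f"{s.subject_id}.csv", index=False, header=header)
    return directory
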