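"""Synthetic two-timepoint morphometric cohorts with known ground truth.

The study population this generator emulates is a community-dwelling elderly
cohort measured twice (baseline and a 2-year follow-up) with three diagnostic
groups — cognitively normal (CN), amnestic MCI (aMCI) and non-amnestic MCI
(naMCI) — at the follow-up group sizes 115 / 42 / 27. Group differences are
planted as sparse mean shifts on a latent standardized scale (Cohen's d
units), optionally with group-specific longitudinal change (per-2-year slope,
also in SD units). Latent values are mapped through affine family transforms
so the observed features carry realistic, wildly different scales (mm for
thickness, thousands of mm^3 for volumes), which makes downstream 0-1
scaling non-trivial.

Noise model per subject i, feature j, group g:

    baseline latent  z_ij = delta_{g,j} + u_ij
    follow-up latent z'_ij = delta_{g,j} + slope_{g,j} + rho*u_ij + sqrt(1-rho^2)*u'_ij

where u, u' are unit-variance noise with an optional within-family
equicorrelation block (nuisance correlation standing in for the unknown real
covariance of morphometrics), and rho is the within-subject test-retest
correlation (default 0.8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .feature_schema import FAMILY_COUNTS, FAMILY_SEP, FeatureTable

#: Affine (location, scale) per family mapping the latent standardized scale
#: to plausible measurement units (mm for widths/thickness, mm^3 for volumes).
FAMILY_TRANSFORMS: dict[str, tuple[float, float]] = {
    "sulcal": (2.2, 0.6),
    "thickness": (2.5, 0.25),
    "gm_volume": (5200.0, 900.0),
    "subcortical": (3800.0, 650.0),
    "wmh": (750.0, 300.0),
}

GROUPS = ("CN", "aMCI", "naMCI")


@dataclass(frozen=True)
class PlantedEffect:
    """A group-specific mean shift on one feature, on the latent (SD) scale."""

    feature_index: int
    group: str
    effect_size: float  # Cohen's d vs the unshifted groups, cross-sectionally
    longitudinal_slope: float = 0.0  # additional shift at follow-up, in SD per 2 years


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults follow the follow-up wave of the emulated study: 115 CN, 42 aMCI,
    27 naMCI subjects and 178 features in the canonical five-family split.
    """

    n_cn: int = 115
    n_amci: int = 42
    n_namci: int = 27
    n_features: int = 178
    planted: tuple[PlantedEffect, ...] = ()
    within_subject_corr: float = 0.8
    within_family_corr: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def group_sizes(self) -> dict[str, int]:
        return {"CN": self.n_cn, "aMCI": self.n_amci, "naMCI": self.n_namci}

    def validate(self) -> None:
        for g, n in self.group_sizes().items():
            if n < 2:
                raise ValueError(f"group {g} needs >= 2 subjects, got {n}")
        if not 0 <= abs(self.within_subject_corr) < 1:
            raise ValueError("|within_subject_corr| must be < 1")
        if not 0 <= self.within_family_corr < 1:
            raise ValueError("within_family_corr must be in [0, 1)")
        seen = set()
        for eff in self.planted:
            if not 0 <= eff.feature_index < self.n_features:
                raise ValueError(
                    f"planted feature index {eff.feature_index} out of range "
                    f"[0, {self.n_features})"
                )
            if eff.group not in GROUPS:
                raise ValueError(f"unknown planted group {eff.group!r}")
            key = (eff.feature_index, eff.group)
            if key in seen:
                raise ValueError(f"duplicate planted effect for {key}")
            seen.add(key)


@dataclass(frozen=True)
class GroundTruth:
    """Which features carry planted signal, per group, with nominal sizes."""

    planted: tuple[PlantedEffect, ...]
    feature_names: tuple[str, ...]

    def planted_indices(self, group: str | None = None) -> tuple[int, ...]:
        return tuple(
            sorted(
                {
                    e.feature_index
                    for e in self.planted
                    if group is None or e.group == group
                }
            )
        )

    def planted_names(self, group: str | None = None) -> tuple[str, ...]:
        return tuple(self.feature_names[i] for i in self.planted_indices(group))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [
                {
                    "feature_index": e.feature_index,
                    "feature_name": self.feature_names[e.feature_index],
                    "group": e.group,
                    "effect_size": e.effect_size,
                    "longitudinal_slope": e.longitudinal_slope,
                }
                for e in self.planted
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def family_layout(n_features: int) -> list[tuple[str, int]]:
    """Per-family widths for an ``n_features``-wide table.

    The canonical 178-feature split is used when it applies; other widths are
    split proportionally (largest-remainder apportionment) so reduced test
    cohorts keep the five-family structure.
    """
    total = sum(FAMILY_COUNTS.values())
    if n_features == total:
        return list(FAMILY_COUNTS.items())
    quotas = {f: n_features * c / total for f, c in FAMILY_COUNTS.items()}
    counts = {f: int(q) for f, q in quotas.items()}
    short = n_features - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda f: quotas[f] - counts[f], reverse=True)
    for f in by_remainder[:short]:
        counts[f] += 1
    return [(f, counts[f]) for f in FAMILY_COUNTS]


def feature_names_for(n_features: int) -> tuple[str, ...]:
    names: list[str] = []
    for fam, count in family_layout(n_features):
        names.extend(f"{fam}{FAMILY_SEP}f{i:03d}" for i in range(count))
    return tuple(names)


def _family_scales(n_features: int) -> tuple[np.ndarray, np.ndarray]:
    loc = np.empty(n_features)
    scale = np.empty(n_features)
    j = 0
    for fam, count in family_layout(n_features):
        loc[j : j + count], scale[j : j + count] = FAMILY_TRANSFORMS[fam]
        j += count
    return loc, scale


def _correlated_noise(
    rng: np.random.Generator, n: int, n_features: int, family_corr: float
) -> np.ndarray:
    """Unit-variance noise with within-family equicorrelation ``family_corr``."""
    e = rng.standard_normal((n, n_features))
    if family_corr <= 0:
        return e
    out = np.empty_like(e)
    j = 0
    for _fam, count in family_layout(n_features):
        shared = rng.standard_normal((n, 1))
        out[:, j : j + count] = (
            np.sqrt(family_corr) * shared + np.sqrt(1 - family_corr) * e[:, j : j + count]
        )
        j += count
    return out


def generate_cohort(
    config: SimulationConfig,
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Draw one cohort: baseline table, follow-up table, and its ground truth.

    Identical configs (including seed) reproduce bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.group_sizes()
    n = sum(sizes.values())
    p = config.n_features

    labels = np.concatenate([np.repeat(g, sizes[g]) for g in GROUPS])
    delta = np.zeros((n, p))
    slope = np.zeros((n, p))
    for eff in config.planted:
        rows = labels == eff.group
        delta[rows, eff.feature_index] += eff.effect_size
        slope[rows, eff.feature_index] += eff.longitudinal_slope

    u_base = _correlated_noise(rng, n, p, config.within_family_corr)
    u_innov = _correlated_noise(rng, n, p, config.within_family_corr)
    rho = config.within_subject_corr
    z_base = delta + config.noise_sd * u_base
    z_wave2 = delta + slope + config.noise_sd * (
        rho * u_base + np.sqrt(1 - rho**2) * u_innov
    )

    loc, scale = _family_scales(p)
    names = feature_names_for(p)
    ids = tuple(f"S{i:04d}" for i in range(n))
    lab = tuple(labels)

    baseline = FeatureTable(ids, names, loc + scale * z_base, "baseline", lab)
    wave2 = FeatureTable(ids, names, loc + scale * z_wave2, "wave2", lab)
    truth = GroundTruth(planted=tuple(config.planted), feature_names=names)
    return baseline, wave2, truth


@dataclass(frozen=True)
class Fixture:
    """A bundled small cohort with documented ground truth and binary task."""

    name: str
    baseline: FeatureTable
    wave2: FeatureTable
    truth: GroundTruth
    positive: str
    negative: str

    def task_table(self, timepoint: str = "baseline") -> FeatureTable:
        """The two-group subset for this fixture's binary task."""
        table = {"baseline": self.baseline, "wave2": self.wave2}[timepoint]
        return table.restrict_labels({self.positive, self.negative})


def _spread_indices(n_features: int, k: int, offset: int = 3) -> list[int]:
    """k planted indices spread across the feature range (hence across families)."""
    return [offset + round(i * (n_features - 2 * offset - 1) / max(k - 1, 1)) for i in range(k)]


_FIXTURE_SEEDS = {"separable": 711001, "null": 711002, "imbalanced": 711003}


def make_fixture(name: str) -> Fixture:
    """Deterministic bundled cohorts for testing and demonstration.

    - ``separable``: 30 CN + 30 aMCI subjects, 150 features, 5 features planted
      at d = 2.5 on the aMCI group (with mild 2-year decline). The groups are
      linearly separable on the planted features.
    - ``null``: 40 CN + 40 aMCI, 100 features, no planted effects and no
      within-family correlation — a pure noise cohort for calibration checks.
    - ``imbalanced``: the study-sized cohort (115 CN / 42 aMCI / 27 naMCI,
      178 features) with moderate planted effects per patient group; its
      naMCI:CN ratio reproduces the 27:115 imbalance.
    """
    if name == "separable":
        idx = _spread_indices(150, 5)
        cfg = SimulationConfig(
            n_cn=30,
            n_amci=30,
            n_namci=2,
            n_features=150,
            planted=tuple(
                PlantedEffect(i, "aMCI", effect_size=2.5, longitudinal_slope=-0.3)
                for i in idx
            ),
            seed=_FIXTURE_SEEDS[name],
        )
        pos, neg = "aMCI", "CN"
    elif name == "null":
        cfg = SimulationConfig(
            n_cn=40,
            n_amci=40,
            n_namci=2,
            n_features=100,
            planted=(),
            within_family_corr=0.0,
            seed=_FIXTURE_SEEDS[name],
        )
        pos, neg = "aMCI", "CN"
    elif name == "imbalanced":
        amci_idx = _spread_indices(178, 5, offset=12)
        namci_idx = _spread_indices(178, 5, offset=30)
        planted = tuple(
            PlantedEffect(i, "aMCI", effect_size=0.8, longitudinal_slope=-0.3)
            for i in amci_idx
        ) + tuple(
            PlantedEffect(i, "naMCI", effect_size=0.6, longitudinal_slope=-0.2)
            for i in namci_idx
            if i not in amci_idx
        )
        cfg = SimulationConfig(planted=planted, seed=_FIXTURE_SEEDS[name])
        pos, neg = "naMCI", "CN"
    else:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_SEEDS)}"
        )
    baseline, wave2, truth = generate_cohort(cfg)
    return Fixture(name, baseline, wave2, truth, positive=pos, negative=neg)
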