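"""Synthetic cohorts of probabilistic-tractography output.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without imaging data:

* each subject has a latent connectivity factor ``s ~ N(1, subject_sd^2)``
  (truncated positive) scaling all of their connection propensities;
* patients receive a global multiplicative deficit on all propensities and
  an extra focal deficit on a designated set of regions;
* streamline counts for seed i hitting target j are independent
  ``Binomial(streams_per_seed, propensity[i, j])`` draws per ordered pair
  — independent rather than multinomial because a probabilistic
  streamline may intersect several targets, so per-target counts are not
  mutually exclusive;
* clinical scores are linear in the latent factor plus Gaussian noise,
  with group means/SDs matching the cohort description the pipeline
  targets; symptom/functioning scales are generated for patients only.

All randomness flows from ``SimulationConfig.seed`` through a
``numpy.random.SeedSequence`` hierarchy, so cohorts are bit-reproducible
and subjects are independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_io import AtlasNodeTable, default_atlas, make_atlas

__all__ = [
    "ClinicalLink", "SimulationConfig", "TractographyRun",
    "default_base_template", "sample_run", "generate_cohort",
    "DEFAULT_FOCAL_REGIONS",
]

# Regions receiving the extra patient deficit by default: structures in
# which patient nodal local efficiency is depressed in the reference
# cohort (basal ganglia, anterior cingulate, thalamus, superior temporal,
# precuneus).
DEFAULT_FOCAL_REGIONS: tuple[str, ...] = (
    "Left-Caudate",
    "Left-Accumbens",
    "Left-Thalamus",
    "Left-RostralAnteriorCingulate",
    "Right-RostralAnteriorCingulate",
    "Left-SuperiorTemporal",
    "Right-SuperiorTemporal",
    "Left-Precuneus",
)


@dataclass(frozen=True)
class ClinicalLink:
    """How one clinical score ties to the latent connectivity factor.

    ``mean``/``sd`` are the patient-group targets for the marginal score
    distribution; ``control_mean``/``control_sd`` the control targets
    (None = score not administered to controls).  ``r`` is the target
    correlation between score and latent factor; the implied slope is
    ``r * sd / subject_sd`` and the noise SD is ``sd * sqrt(1 - r^2)``,
    so the marginal SD is preserved whatever the link strength.
    """

    mean: float
    sd: float
    r: float
    control_mean: float | None = None
    control_sd: float | None = None


def _default_clinical_links() -> dict[str, ClinicalLink]:
    return {
        "fsiq_raw": ClinicalLink(97.8, 15.5, 0.15, 120.1, 9.2),
        "fsiq_adjusted": ClinicalLink(100.0, 15.0, 0.15, 115.0, 10.0),
        "ctt1_t": ClinicalLink(48.6, 14.4, 0.30, 54.5, 7.5),
        "ctt2_t": ClinicalLink(47.0, 13.7, 0.25, 63.8, 20.5),
        "panss_total": ClinicalLink(61.0, 14.7, -0.10),
        "gaf": ClinicalLink(39.8, 19.3, 0.10),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 48
    n_controls: int = 24
    n_nodes: int = 87
    streams_per_seed: int = 5000
    base_template: np.ndarray | None = field(default=None, repr=False)
    global_deficit: float = 0.95
    focal_deficit: float = 0.85
    focal_regions: Sequence[str] = DEFAULT_FOCAL_REGIONS
    subject_sd: float = 0.05
    clinical_links: dict[str, ClinicalLink] = field(
        default_factory=_default_clinical_links
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not (0.0 < self.global_deficit <= 1.0):
            raise ValueError("global_deficit must be in (0, 1]")
        if not (0.0 < self.focal_deficit <= 1.0):
            raise ValueError("focal_deficit must be in (0, 1]")
        if self.subject_sd < 0.0:
            raise ValueError("subject_sd must be nonnegative")
        if self.base_template is not None:
            T = np.asarray(self.base_template, dtype=float)
            if T.shape != (self.n_nodes, self.n_nodes):
                raise ValueError("base_template shape must match n_nodes")
            if not np.allclose(T, T.T, rtol=0.0, atol=0.0):
                raise ValueError("base_template must be symmetric")
            if np.any(np.diag(T) != 0.0):
                raise ValueError("base_template diagonal must be zero")
            if np.any((T < 0.0) | (T > 1.0)):
                raise ValueError("base_template entries must lie in [0, 1]")
            if not np.any(T > 0.0):
                raise ValueError("base_template is degenerate (all zeros)")

    def atlas(self) -> AtlasNodeTable:
        return make_atlas(self.n_nodes)

    def template(self, atlas: AtlasNodeTable | None = None) -> np.ndarray:
        if self.base_template is not None:
            return np.asarray(self.base_template, dtype=float)
        return default_base_template(atlas or self.atlas())


@dataclass
class TractographyRun:
    """Directed streamline counts for one subject.

    ``counts[i, j]`` = streamlines seeded in ROI i that passed through
    ROI j; ``waytotals[i]`` = streamlines generated from seed i (the
    way-total, the denominator of connection probability).
    """

    subject_id: str
    counts: np.ndarray
    waytotals: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.counts, dtype=np.int64)
        w = np.asarray(self.waytotals, dtype=np.int64)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("counts must be square")
        if w.shape != (C.shape[0],):
            raise ValueError("waytotals length must match counts")
        if np.any(C < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(np.diag(C) != 0):
            raise ValueError("counts diagonal must be zero")
        if np.any(C > w[:, None]):
            raise ValueError("counts cannot exceed the seed's way-total")
        self.counts, self.waytotals = C, w

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


def default_base_template(atlas: AtlasNodeTable) -> np.ndarray:
    """Deterministic block-structured connection propensities.

    Propensity is higher within a hemisphere, higher still between
    homologous left/right structures, and lower across hemispheres, with
    a fixed-seed lognormal jitter breaking ties.  The resulting networks
    are dense (nearly all pairs receive a positive propensity), matching
    tractography-derived connectomes in which a 10% threshold still
    leaves nodal degrees in the high tens on 87 nodes, and the overall
    propensity level is scaled so mean connectivity strength lands near
    0.35.
    """
    n = atlas.n_nodes
    hemi = list(atlas.table["hemisphere"])
    cls = list(atlas.table["region_class"])
    stem = [nm.split("-", 1)[-1] for nm in atlas.names]
    T = np.empty((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            if stem[i] == stem[j] and hemi[i] != hemi[j]:
                base = 0.70  # homologous pair
            elif hemi[i] == hemi[j]:
                base = 0.57 if cls[i] == cls[j] else 0.43
            else:
                base = 0.28
            T[i, j] = base
    rng = np.random.default_rng(19680801)  # frozen: part of the template
    jitter = np.exp(rng.normal(0.0, 0.25, size=(n, n)))
    jitter = np.sqrt(jitter * jitter.T)  # keep symmetry
    T = np.clip(T * jitter, 0.01, 0.95)
    T = (T + T.T) / 2.0
    np.fill_diagonal(T, 0.0)
    return T


def sample_run(
    propensity: np.ndarray,
    config: SimulationConfig,
    subject_seed: int | np.random.SeedSequence,
    subject_id: str = "",
) -> TractographyRun:
    """Draw one tractography run from per-pair connection propensities.

    Counts are independent Binomial(streams_per_seed, propensity[i, j])
    per ordered pair; way-totals all equal ``streams_per_seed``.
    """
    P = np.asarray(propensity, dtype=float)
    if np.any((P < 0.0) | (P > 1.0)):
        raise ValueError("propensity entries must lie in [0, 1]")
    if np.any(np.diag(P) != 0.0):
        raise ValueError("propensity diagonal must be zero")
    rng = np.random.default_rng(subject_seed)
    counts = rng.binomial(config.streams_per_seed, P)
    np.fill_diagonal(counts, 0)
    waytotals = np.full(P.shape[0], config.streams_per_seed, dtype=np.int64)
    return TractographyRun(subject_id, counts, waytotals)


def _truncated_positive_normal(
    rng: np.random.Generator, mean: float, sd: float
) -> float:
    if sd == 0.0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0.0:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[TractographyRun], dict]:
    """Generate a full cohort: table of subjects, runs, generating truth.

    Returns ``(cohort, runs, true_params)`` where ``cohort`` is a
    DataFrame (subject_id, group, clinical scores; PANSS/GAF blank for
    controls), ``runs`` one :class:`TractographyRun` per subject, and
    ``true_params`` records every generating value (latent factors,
    deficits, template, per-subject propensities) for recovery tests.
    """
    atlas = config.atlas()
    template = config.template(atlas)
    if not np.any(template > 0.0):
        raise ValueError("base template is degenerate (all zeros)")

    known = set(atlas.names)
    focal = [r for r in config.focal_regions if r in known]
    focal_idx = atlas.index_of(focal) if focal else np.array([], dtype=int)
    focal_mask = np.ones_like(template)
    if focal_idx.size:
        focal_mask[focal_idx, :] *= config.focal_deficit
        focal_mask[:, focal_idx] *= config.focal_deficit
        # a pair with both ends focal gets the factor twice; cap at once
        both = np.ix_(focal_idx, focal_idx)
        focal_mask[both] = config.focal_deficit

    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_patients + config.n_controls
    child_seeds = ss.spawn(n_total + 1)
    score_rng = np.random.default_rng(child_seeds[-1])

    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    rows, runs = [], []
    latent = {}
    propensities = {}
    for k, group in enumerate(groups):
        sid = f"{'spr' if group == 'patient' else 'hc'}{k:03d}"
        sub_ss = child_seeds[k]
        sub_rng = np.random.default_rng(sub_ss)
        s = _truncated_positive_normal(sub_rng, 1.0, config.subject_sd)
        P = template * s
        if group == "patient":
            P = P * config.global_deficit * focal_mask
        P = np.clip(P, 0.0, 1.0)
        np.fill_diagonal(P, 0.0)
        runs.append(sample_run(P, config, sub_rng, subject_id=sid))
        latent[sid] = s
        propensities[sid] = P

        row: dict[str, object] = {"subject_id": sid, "group": group}
        for score, link in config.clinical_links.items():
            if group == "control":
                if link.control_mean is None:
                    row[score] = np.nan
                    continue
                mean, sd = link.control_mean, link.control_sd or link.sd
            else:
                mean, sd = link.mean, link.sd
            if config.subject_sd > 0.0 and link.r != 0.0:
                slope = link.r * sd / config.subject_sd
                noise_sd = sd * np.sqrt(max(0.0, 1.0 - link.r**2))
            else:
                slope, noise_sd = 0.0, sd
            row[score] = mean + slope * (s - 1.0) + score_rng.normal(0.0, noise_sd)
        rows.append(row)

    cohort = pd.DataFrame(rows)
    true_params = {
        "config": {
            "n_patients": config.n_patients,
            "n_controls": config.n_controls,
            "n_nodes": config.n_nodes,
            "streams_per_seed": config.streams_per_seed,
            "global_deficit": config.global_deficit,
            "focal_deficit": config.focal_deficit,
            "focal_regions": list(focal),
            "subject_sd": config.subject_sd,
            "seed": config.seed,
        },
        "latent_factor": latent,
        "template": template,
        "propensity": propensities,
    }
    return cohort, runs, true_params


def null_config(**overrides) -> SimulationConfig:
    """A configuration with no group effect (all deficit factors 1)."""
    overrides.setdefault("global_deficit", 1.0)
    overrides.setdefault("focal_deficit", 1.0)
    return SimulationConfig(**overrides)
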