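"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes for a tau-PET MCI/NC
cohort split into four APOE-e4 x CSF-T-Tau groups: regional uptake with age,
sex and whole-brain confounds, block-modular inter-regional covariance
induced by latent community factors (guaranteeing a positive semi-definite
covariance for any configuration), a planted group-mean elevation in
designated temporal/limbic regions of one group, a positive uptake-FAQ
coupling in that group, and a CSF-T-Tau coupling to two regions.

Regional uptake for subject i, region r in module m(r):

    x_ir = mu + b_age (age_i - abar) + b_sex sex_i + b_gl g_i
           + sigma [ sqrt(rb) u_i + sqrt(rw - rb) f_im(r) + sqrt(1 - rw) e_ir ]
           + sigma * effect_size * 1[r planted, i in affected group] + ...

with u, f, e standard normal, so any two regions correlate ~rw within a
module and ~rb between modules (before confounds). sigma is the structured
noise scale (``noise_sd``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .atlas import RegionAtlas, load_aal90
from .cohort import GROUPS, CohortTable, SubjectRecord, TTAU_CUTOFF

#: planted-elevation regions: bilateral parahippocampal/fusiform/temporal
#: plus left amygdala, the regions elevated in the APOE4+T+ group
DEFAULT_EFFECT_REGIONS = (
    "ParaHippocampal_L", "ParaHippocampal_R", "Amygdala_L",
    "Fusiform_L", "Fusiform_R", "Temporal_Sup_R",
    "Temporal_Mid_L", "Temporal_Mid_R", "Temporal_Inf_L", "Temporal_Inf_R")

DEFAULT_CSF_REGIONS = ("Olfactory_L", "ParaHippocampal_R")

_TABLE_DEFAULTS = {
    "group_sizes": {"A4-T-": 103, "A4+T+": 34, "A4+T-": 44, "A4-T+": 44},
    "age_mean_sd": {"A4-T-": (77.8, 6.5), "A4+T+": (76.7, 7.1),
                    "A4+T-": (75.7, 7.1), "A4-T+": (79.1, 7.0)},
    "male_fraction": {"A4-T-": 61 / 103, "A4+T+": 16 / 34,
                      "A4+T-": 20 / 44, "A4-T+": 19 / 44},
    "mci_fraction": {"A4-T-": 54 / 103, "A4+T+": 16 / 34,
                     "A4+T-": 18 / 44, "A4-T+": 21 / 44},
    "abeta_pos_fraction": {"A4-T-": 90 / 103, "A4+T+": 30 / 34,
                           "A4+T-": 37 / 44, "A4-T+": 38 / 44},
    "faq_baseline": {"A4-T-": 1.68, "A4+T+": 4.35, "A4+T-": 1.85, "A4-T+": 1.98},
    "mmse_mean_sd": {"A4-T-": (27.76, 1.87), "A4+T+": (28.33, 1.55),
                     "A4+T-": (28.42, 1.41), "A4-T+": (28.70, 1.35)},
}


def default_module_assignment(atlas: RegionAtlas | None = None,
                              n_modules: int = 5) -> dict[str, int]:
    """Contiguous atlas-order blocks as planted communities.

    Atlas order groups anatomically related regions (frontal, limbic,
    occipital, parietal/subcortical, temporal), so contiguous blocks are a
    reasonable stand-in for lobar covariance modules.
    """
    atlas = atlas or load_aal90()
    n = len(atlas)
    size = math.ceil(n / n_modules)
    return {name: i // size for i, name in enumerate(atlas.names)}


@dataclass
class SimulationConfig:
    """Generator configuration; defaults are the study conditions.

    noise_sd is the scale sigma of the structured per-region variation, and
    effect_size / csf_coupling are expressed in units of sigma.
    """

    group_sizes: dict = field(default_factory=lambda: dict(_TABLE_DEFAULTS["group_sizes"]))
    age_mean_sd: dict = field(default_factory=lambda: dict(_TABLE_DEFAULTS["age_mean_sd"]))
    male_fraction: dict = field(default_factory=lambda: dict(_TABLE_DEFAULTS["male_fraction"]))
    mci_fraction: dict = field(default_factory=lambda: dict(_TABLE_DEFAULTS["mci_fraction"]))
    abeta_pos_fraction: dict = field(default_factory=lambda: dict(_TABLE_DEFAULTS["abeta_pos_fraction"]))
    module_assignment: dict | None = None     # region -> community index
    within_module_r: float = 0.5
    between_module_r: float = 0.1
    spatial_r: float = 0.25                   # share of variance from smooth field
    effect_regions: tuple = DEFAULT_EFFECT_REGIONS
    effect_group: str = "A4+T+"
    effect_size: float = 1.0                  # planted mean shift, in sigma units
    faq_coupling: float = 20.0                # FAQ points per unit mean uptake
    faq_noise_sd: float = 4.5
    faq_baseline: dict = field(default_factory=lambda: dict(_TABLE_DEFAULTS["faq_baseline"]))
    csf_regions: tuple = DEFAULT_CSF_REGIONS
    csf_coupling: float = 0.8                 # sigma units per within-group SD of T-Tau
    mmse_mean_sd: dict = field(default_factory=lambda: dict(_TABLE_DEFAULTS["mmse_mean_sd"]))
    baseline_uptake: float = 1.5
    noise_sd: float = 0.25
    confound_slopes: dict = field(default_factory=lambda: {"age": 0.01, "sex": 0.05,
                                                           "global": 1.0})
    ttau_abnormal_mean_sd: tuple = (420.0, 80.0)
    ttau_normal_mean_sd: tuple = (220.0, 50.0)
    seed: int | None = None

    def validate(self, atlas: RegionAtlas) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if n <= 0:
                raise ValueError(f"group size for {g!r} must be positive")
        rw, rb = self.within_module_r, self.between_module_r
        if not (abs(rw) < 1 and abs(rb) < 1):
            raise ValueError("module correlations must have magnitude < 1")
        if rw <= rb:
            raise ValueError("within_module_r must exceed between_module_r")
        if rb < 0:
            raise ValueError("between_module_r must be non-negative")
        if not 0 <= self.spatial_r < 1 or rw + self.spatial_r >= 1:
            raise ValueError("need 0 <= spatial_r and within_module_r + spatial_r < 1")
        for coll, what in ((self.effect_regions, "effect"), (self.csf_regions, "csf")):
            unknown = set(coll) - set(atlas.names)
            if unknown:
                raise ValueError(f"unknown {what} region(s): {sorted(unknown)}")
        if self.effect_group not in GROUPS:
            raise ValueError(f"unknown effect group {self.effect_group!r}")
        if self.noise_sd <= 0 or self.faq_noise_sd < 0:
            raise ValueError("noise scales must be positive")
        for g in self.group_sizes:
            for d in (self.age_mean_sd, self.male_fraction, self.mci_fraction,
                      self.abeta_pos_fraction, self.faq_baseline, self.mmse_mean_sd):
                if g not in d:
                    raise ValueError(f"missing per-group parameter for {g!r}")


@dataclass
class PlantedTruth:
    """Ground truth the generator planted, for parameter-recovery tests."""

    module_membership: np.ndarray             # region index -> community
    effect_regions: dict                      # group -> tuple of region labels
    effect_size: float
    faq_group: str
    faq_slope: float
    csf_regions: tuple
    csf_group: str


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out >= hi)
    return out


def generate_cohort(config: SimulationConfig | None = None,
                    atlas: RegionAtlas | None = None,
                    seed=None) -> tuple[CohortTable, PlantedTruth]:
    """Draw one cohort from the configured generative process.

    ``seed`` overrides ``config.seed`` when given; the draw is reproducible
    for a fixed seed.
    """
    config = config or SimulationConfig()
    atlas = atlas or load_aal90()
    config.validate(atlas)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N = len(atlas)
    modules = config.module_assignment or default_module_assignment(atlas)
    membership = np.asarray([modules[name] for name in atlas.names])
    n_modules = int(membership.max()) + 1
    rw, rb, sigma = config.within_module_r, config.between_module_r, config.noise_sd
    eff_idx = np.asarray(atlas.indices(config.effect_regions), dtype=int)
    csf_idx = np.asarray(atlas.indices(config.csf_regions), dtype=int)
    slopes = config.confound_slopes
    abar = float(np.mean([m for m, _ in config.age_mean_sd.values()]))

    subjects: list[SubjectRecord] = []
    blocks: list[np.ndarray] = []
    sid = 0
    for group in GROUPS:
        if group not in config.group_sizes:
            continue
        n = int(config.group_sizes[group])
        a_mean, a_sd = config.age_mean_sd[group]
        age = rng.normal(a_mean, a_sd, n)
        sex = (rng.random(n) < config.male_fraction[group]).astype(int)
        g_lat = rng.normal(0.0, 0.1, n)
        u = rng.normal(size=n)
        f = rng.normal(size=(n, n_modules))
        eps = rng.normal(size=(n, N))
        # spatially smooth field: moving average over atlas index, so
        # neighboring regions share noise (tracer uptake is spatially smooth);
        # keeps group networks connected at low sparsity
        rsp = config.spatial_r
        raw = rng.normal(size=(n, N + 2))
        smooth = (raw[:, :-2] + raw[:, 1:-1] + raw[:, 2:]) / np.sqrt(3.0)
        latent = (np.sqrt(rb) * u[:, None]
                  + np.sqrt(rw - rb) * f[:, membership]
                  + np.sqrt(rsp) * smooth
                  + np.sqrt(1.0 - rw - rsp) * eps)
        x = (config.baseline_uptake
             + slopes.get("age", 0.0) * (age[:, None] - abar)
             + slopes.get("sex", 0.0) * sex[:, None]
             + slopes.get("global", 0.0) * g_lat[:, None]
             + sigma * latent)
        if group == config.effect_group and config.effect_size:
            x[:, eff_idx] += config.effect_size * sigma

        abnormal = group.endswith("T+")
        mean_sd = (config.ttau_abnormal_mean_sd if abnormal
                   else config.ttau_normal_mean_sd)
        lo, hi = ((TTAU_CUTOFF, np.inf) if abnormal else (1.0, TTAU_CUTOFF))
        ttau = _truncated_normal(rng, *mean_sd, lo, hi, n)
        if group == config.effect_group and config.csf_coupling and n > 1:
            z = (ttau - ttau.mean()) / ttau.std()
            x[:, csf_idx] += config.csf_coupling * sigma * z[:, None]

        faq = np.full(n, config.faq_baseline[group])
        if group == config.effect_group and config.faq_coupling:
            u_eff = x[:, eff_idx].mean(axis=1)
            faq = faq + config.faq_coupling * (u_eff - u_eff.mean())
        faq = np.clip(np.rint(faq + rng.normal(0.0, config.faq_noise_sd, n)), 0, 30)
        m_mean, m_sd = config.mmse_mean_sd[group]
        mmse = np.clip(np.rint(rng.normal(m_mean, m_sd, n)), 0, 30)
        mci = rng.random(n) < config.mci_fraction[group]
        abeta = rng.random(n) < config.abeta_pos_fraction[group]

        for i in range(n):
            subjects.append(SubjectRecord(
                id=f"S{sid:04d}", group=group, age=float(age[i]),
                sex=int(sex[i]), diagnosis="MCI" if mci[i] else "NC",
                faq=float(faq[i]), mmse=float(mmse[i]),
                csf_ttau=float(ttau[i]),
                abeta_status="positive" if abeta[i] else "negative"))
            sid += 1
        blocks.append(x)

    cohort = CohortTable(atlas, subjects, np.vstack(blocks))
    truth = PlantedTruth(
        module_membership=membership,
        effect_regions={config.effect_group: tuple(config.effect_regions)}
        if config.effect_size else {},
        effect_size=config.effect_size,
        faq_group=config.effect_group, faq_slope=config.faq_coupling,
        csf_regions=tuple(config.csf_regions), csf_group=config.effect_group)
    return cohort, truth


def null_pair_config(n_per_group: int,
                     labels: tuple[str, str] = ("A4-T-", "A4-T+"),
                     **overrides) -> SimulationConfig:
    """Config for two groups drawn from one identical generative process."""
    if n_per_group < 10:
        raise ValueError("n_per_group must be at least 10")
    base = dict(
        group_sizes={labels[0]: n_per_group, labels[1]: n_per_group},
        age_mean_sd={g: (77.8, 6.5) for g in labels},
        male_fraction={g: 0.5 for g in labels},
        mci_fraction={g: 0.5 for g in labels},
        abeta_pos_fraction={g: 0.8 for g in labels},
        faq_baseline={g: 2.0 for g in labels},
        mmse_mean_sd={g: (28.0, 1.6) for g in labels},
        effect_size=0.0, faq_coupling=0.0, csf_coupling=0.0)
    base.update(overrides)
    return SimulationConfig(**base)


def sample_null_pair(n_per_group: int, seed=None,
                     labels: tuple[str, str] = ("A4-T-", "A4-T+"),
                     config: SimulationConfig | None = None) -> CohortTable:
    """Cohort of two exchangeable groups (identical process, no effects)."""
    cfg = config or null_pair_config(n_per_group, labels)
    cohort, _ = generate_cohort(cfg, seed=seed)
    return cohort


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    d = asdict(config)
    d["effect_regions"] = list(d["effect_regions"])
    d["csf_regions"] = list(d["csf_regions"])
    for k in ("age_mean_sd", "mmse_mean_sd"):
        d[k] = {g: list(v) for g, v in d[k].items()}
    d["ttau_abnormal_mean_sd"] = list(d["ttau_abnormal_mean_sd"])
    d["ttau_normal_mean_sd"] = list(d["ttau_normal_mean_sd"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    for k in ("effect_regions", "csf_regions", "ttau_abnormal_mean_sd",
              "ttau_normal_mean_sd"):
        if k in d:
            d[k] = tuple(d[k])
    for k in ("age_mean_sd", "mmse_mean_sd"):
        if k in d:
            d[k] = {g: tuple(v) for g, v in d[k].items()}
    return SimulationConfig(**d)
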