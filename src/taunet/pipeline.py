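"""End-to-end pipeline: cohort -> networks -> metrics -> inference -> tables.

``run_full_pipeline`` sequences every stage of the analysis on one cohort
and writes tidy delimited outputs plus a manifest with the resolved
configuration and a content hash of every output file, so a run is fully
reproducible from its output directory. A single global seed is expanded
into independent per-task streams, so any stage rerun in isolation with its
own stream reproduces its piece of the full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, metrics, regional
from .cohort import GROUPS, read_cohort, split_by_group
from .demographics import demographics_table
from .network import build_group_network

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    values_path: str
    metadata_path: str
    out_dir: str
    reference_group: str = "A4-T-"
    comparison_groups: tuple | None = None      # default: all other groups present
    global_metrics: tuple = ("cp", "lp", "q")
    nodal_metrics: tuple = ("bc", "degree")
    grid: tuple = inference.DEFAULT_GRID
    s_fixed: float = inference.DEFAULT_S_FIXED
    n_perm: int = inference.DEFAULT_N_PERM
    nodal_n_perm: int | None = None
    alpha: float = 0.05
    fdr_q: float = 0.05
    adjust_covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.size == 0 or np.any((grid <= 0) | (grid > 1)) or np.any(np.diff(grid) <= 0):
            raise ValueError("sparsity grid must be strictly increasing within (0, 1]")
        if self.n_perm < 100 or (self.nodal_n_perm or self.n_perm) < 100:
            raise ValueError("n_perm must be at least 100")
        if not 0 < self.s_fixed <= 1:
            raise ValueError("s_fixed must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("comparison_groups", "global_metrics", "nodal_metrics", "grid"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _task_seed(base_seed: int, label: str):
    """Independent, order-insensitive seed stream for one named task."""
    digest = hashlib.sha256(label.encode()).digest()[:4]
    return np.random.SeedSequence([base_seed, int.from_bytes(digest, "big")])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


def run_full_pipeline(config: RunConfig) -> Path:
    """Run every analysis stage; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, *parts: str) -> None:
        path = out.joinpath(*parts)
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
        written.append(path)

    def stage(name):
        log.info("stage: %s", name)
        return name

    current = stage("read_cohort")
    try:
        cohort = read_cohort(config.values_path, config.metadata_path)
        by_group = split_by_group(cohort)
        ref = config.reference_group
        if ref not in by_group:
            raise ValueError(f"reference group {ref!r} not in cohort")
        comps = (list(config.comparison_groups) if config.comparison_groups
                 else [g for g in by_group if g != ref])

        current = stage("demographics")
        save(demographics_table(cohort, ref), "demographics.csv")

        current = stage("networks")
        nets = {g: build_group_network(c, group=g) for g, c in by_group.items()}
        for g, net in nets.items():
            df = pd.DataFrame(net.R, columns=list(cohort.atlas.names))
            df.insert(0, "region", list(cohort.atlas.names))
            save(df, "networks", f"corr_{g}.csv")

        current = stage("metric_curves")
        save(metrics.metric_curves(nets, config.grid), "metrics", "global_curves.csv")

        current = stage("permutation_global")
        for g in comps:
            for m in config.global_metrics:
                res = inference.permutation_test_global(
                    cohort, ref, g, m, grid=config.grid, n_perm=config.n_perm,
                    seed=_task_seed(config.seed, f"global:{m}:{g}"),
                    alpha=config.alpha)
                save(res.to_frame(), "permtest", f"global_{m}_{ref}_vs_{g}.csv")

        current = stage("permutation_nodal")
        for g in comps:
            for m in config.nodal_metrics:
                df = inference.permutation_test_nodal(
                    cohort, ref, g, m, s_fixed=config.s_fixed,
                    n_perm=config.nodal_n_perm or config.n_perm,
                    seed=_task_seed(config.seed, f"nodal:{m}:{g}"),
                    fdr_q=config.fdr_q)
                save(df, "permtest", f"nodal_{m}_{ref}_vs_{g}.csv")

        current = stage("regional")
        anova = regional.anova_regions(cohort, config.adjust_covariates, config.fdr_q)
        save(anova, "regional", "anova.csv")
        contrasts = regional.posthoc_contrasts(cohort, ref, config.adjust_covariates,
                                               config.fdr_q)
        for g, df in contrasts.items():
            save(df, "regional", f"posthoc_{g}.csv")

        current = stage("correlations")
        for g in comps:
            mask = contrasts.get(g)
            regions = (mask.loc[mask["significant"], "region"].tolist()
                       if mask is not None else [])
            if regions:
                save(regional.correlate_with_score(cohort, regions, "faq", g),
                     "regional", f"faq_corr_{g}.csv")
            else:
                save(pd.DataFrame(columns=["region", "r", "p", "n"]),
                     "regional", f"faq_corr_{g}.csv")
            save(regional.correlate_csf_pet(cohort, g), "regional", f"csf_corr_{g}.csv")
    except Exception as exc:
        raise StageError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run.

    Lists significant sparsities per global metric, significant nodes, and
    significant regions/correlations; explicit 'none' entries where nothing
    was significant. Missing outputs are listed, not fatal.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"Run report: {run_dir}",
             f"seed: {manifest['seed']}"]
    missing = []
    for rel in sorted(manifest["outputs"]):
        path = run_dir / rel
        if not path.exists():
            missing.append(rel)
            continue
        if rel.startswith("permtest/global_"):
            df = pd.read_csv(path)
            sig = df.loc[df["significant"], "sparsity"].tolist()
            lines.append(f"{rel}: significant sparsities "
                         f"{sig if sig else 'none'}")
        elif rel.startswith("permtest/nodal_"):
            df = pd.read_csv(path)
            sig = df.loc[df["significant"], "region"].tolist()
            lines.append(f"{rel}: significant regions {sig if sig else 'none'}")
        elif rel.startswith("regional/anova"):
            df = pd.read_csv(path)
            sig = df.loc[df["significant"], "region"].tolist()
            lines.append(f"{rel}: significant regions {sig if sig else 'none'}")
        elif rel.startswith("regional/posthoc_"):
            df = pd.read_csv(path)
            sig = df.loc[df["significant"], "region"].tolist() if len(df) else []
            lines.append(f"{rel}: significant regions {sig if sig else 'none'}")
        elif rel.startswith("regional/faq_corr") or rel.startswith("regional/csf_corr"):
            df = pd.read_csv(path)
            sig = (df.loc[df["p"] < 0.05, "region"].tolist() if len(df) else [])
            lines.append(f"{rel}: p<0.05 regions {sig if sig else 'none'}")
        elif rel == "demographics.csv":
            lines.append(f"{rel}: present")
    if missing:
        lines.append(f"missing outputs: {missing}")
    return "\n".join(lines)
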