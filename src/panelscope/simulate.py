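"""Synthetic labeled count matrices with planted panel-expressing subsets.

The generator emulates the kind of data the evaluation procedure consumes —
a cell x gene count matrix with cluster labels, in which designated subsets
over-express designated marker panels — without any download.  Counts are
negative binomial with mean/dispersion parameterization::

    counts ~ NB(mean = mu0 * fold_change^{gene planted for this cell} * lib,
                variance = mean + mean^2 / phi)

where ``lib`` is a per-cell log-normal library-size factor (unit mean,
log-sd ``sigma_lib``).  The NB is the canonical over-dispersed model for
scRNA-seq counts.  Deliberately not simulated: batch effects, ambient RNA,
doublets, gene-gene correlation beyond the planted panels.

``default_study_config`` fixes the study conditions used throughout the
package's simulation experiments: 32 subsets x 200 cells with one planted
3-gene panel per subset, so 32 panels are co-evaluated — the same cohort
size as the reference healthy-blood group.  The co-evaluated cohort must be
this large for the specificity call to be attainable at all: the
classification threshold floor(0.1*N) only clears the panel's own
population (which always occupies one bin) once N reaches a few tens.
Remaining knobs: fold-change 50, mu0 = 1.5, phi = 2, sigma_lib = 0.3, 900
genes in total (a scaled-down gene space on which the standard QC
thresholds remain meaningful: background detected-gene counts land around
600).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData

from .matrix import make_labeled
from .panels import GenePanel, PanelRegistry

__all__ = [
    "PanelPlan",
    "SimulationConfig",
    "StudyResult",
    "simulate",
    "simulate_study",
    "default_study_config",
    "truth_registry",
]


@dataclass(frozen=True)
class PanelPlan:
    genes: tuple[int, ...]  # column indices into the simulated gene space
    subsets: tuple[str, ...]  # labels of expressing subsets
    fold_change: float  # > 1


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int
    subsets: tuple[tuple[str, int], ...]  # (label, n_cells)
    panels: dict[str, PanelPlan] = field(default_factory=dict)
    mu0: float = 1.5
    phi: float = 2.0
    sigma_lib: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.sigma_lib < 0:
            raise ValueError("sigma_lib must be >= 0")
        labels = [s for s, _ in self.subsets]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate subset labels")
        if any(n < 1 for _, n in self.subsets):
            raise ValueError("every subset needs >= 1 cell")
        for name, plan in self.panels.items():
            if plan.fold_change <= 1:
                raise ValueError(f"panel {name!r}: fold_change must be > 1")
            if any(g < 0 or g >= self.n_genes for g in plan.genes):
                raise ValueError(f"panel {name!r}: gene index out of range")
            unknown = set(plan.subsets) - set(labels)
            if unknown:
                raise ValueError(f"panel {name!r}: unregistered expressing subsets {unknown}")

    @property
    def n_cells(self) -> int:
        return sum(n for _, n in self.subsets)


def _gene_names(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def truth_registry(config: SimulationConfig) -> PanelRegistry:
    """Registry of the planted panels, in the simulated gene namespace."""
    names = _gene_names(config.n_genes)
    reg = PanelRegistry()
    for name, plan in config.panels.items():
        reg.add(GenePanel(name=name, genes=tuple(names[g] for g in plan.genes), description="planted"))
    return reg


def simulate(config: SimulationConfig, *, sample_id: str = "s0") -> tuple[AnnData, dict]:
    """Draw one labeled count matrix; byte-identical given the same config/seed.

    The ground-truth sidecar records which panels are planted where and at
    what fold-change, so downstream checks never re-derive it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    labels: list[str] = []
    for label, n in config.subsets:
        labels.extend([label] * n)
    labels_arr = np.array(labels)
    n_cells = len(labels_arr)

    mu = np.full((n_cells, config.n_genes), config.mu0, dtype=float)
    for plan in config.panels.values():
        cell_mask = np.isin(labels_arr, plan.subsets)
        if cell_mask.any():
            mu[np.ix_(cell_mask, np.array(plan.genes))] *= plan.fold_change
    if config.sigma_lib > 0:
        lib = rng.lognormal(mean=-config.sigma_lib**2 / 2, sigma=config.sigma_lib, size=n_cells)
        mu *= lib[:, None]

    p = config.phi / (config.phi + mu)
    counts = rng.negative_binomial(config.phi, p).astype(np.int32)

    adata = make_labeled(
        counts,
        _gene_names(config.n_genes),
        [f"{sample_id}_c{i:05d}" for i in range(n_cells)],
        labels_arr,
        samples=[sample_id] * n_cells,
    )
    gene_names = _gene_names(config.n_genes)
    truth = {
        "seed": config.seed,
        "sample_id": sample_id,
        "panels": {
            name: {
                "genes": [gene_names[g] for g in plan.genes],
                "subsets": list(plan.subsets),
                "fold_change": plan.fold_change,
            }
            for name, plan in config.panels.items()
        },
        "subset_sizes": {label: int(n) for label, n in config.subsets},
    }
    return adata, truth


def default_study_config(seed: int = 0, *, fold_change: float = 50.0) -> SimulationConfig:
    """The package's reference study conditions (see module docstring)."""
    n_subsets, cells_per_subset, genes_per_panel = 32, 200, 3
    subsets = tuple((f"s{i}", cells_per_subset) for i in range(n_subsets))
    panels: dict[str, PanelPlan] = {}
    for i in range(n_subsets):
        genes = tuple(range(i * genes_per_panel, (i + 1) * genes_per_panel))
        panels[f"P_s{i}"] = PanelPlan(genes=genes, subsets=(f"s{i}",), fold_change=fold_change)
    return SimulationConfig(n_genes=900, subsets=subsets, panels=panels, seed=seed)


# ---------------------------------------------------------------------------
# multi-sample studies


@dataclass
class StudyResult:
    samples: dict[str, AnnData] | None  # None when counts were not drawn
    proportions: pd.DataFrame  # sample, group, panel, proportion
    group_of: dict[str, str]
    truth: dict


def simulate_study(
    config: SimulationConfig,
    groups: Sequence[str],
    samples_per_group: int | Mapping[str, int],
    *,
    shifts: Mapping[tuple[str, str], float] | None = None,
    concentration: float = 200.0,
    cells_per_sample: int | None = None,
    counts: bool = True,
    seed: int | None = None,
) -> StudyResult:
    """Simulate a multi-sample cohort with group-level proportion shifts.

    Per sample, subset proportions are drawn from a Dirichlet centred on the
    group-level base proportions (config subset sizes, optionally multiplied
    by ``shifts[(group, subset)]`` and renormalized); ``concentration``
    controls sample-to-sample wobble.  With ``counts=False`` only the
    ground-truth proportion table is produced (cheap null/power studies).

    A group with fewer than 2 samples is rejected here because every
    downstream comparison needs >= 2 samples per group.
    """
    config.validate()
    if isinstance(samples_per_group, int):
        samples_per_group = {g: samples_per_group for g in groups}
    for g in groups:
        if samples_per_group.get(g, 0) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    subset_labels = [s for s, _ in config.subsets]
    base = np.array([n for _, n in config.subsets], dtype=float)
    base /= base.sum()
    n_cells = cells_per_sample or config.n_cells

    # panel -> expressing subsets, for the proportion table; unplanted subsets
    # appear under their own label
    panel_of_subset: dict[str, list[str]] = {s: [] for s in subset_labels}
    for name, plan in config.panels.items():
        for s in plan.subsets:
            panel_of_subset[s].append(name)

    samples: dict[str, AnnData] | None = {} if counts else None
    rows = []
    group_of: dict[str, str] = {}
    for group in groups:
        props_g = base.copy()
        if shifts:
            for i, s in enumerate(subset_labels):
                props_g[i] *= shifts.get((group, s), 1.0)
            props_g /= props_g.sum()
        for k in range(samples_per_group[group]):
            sample_id = f"{group}_{k}"
            group_of[sample_id] = group
            props = rng.dirichlet(concentration * props_g)
            sizes = rng.multinomial(n_cells, props)
            for s, frac in zip(subset_labels, sizes / n_cells):
                targets = panel_of_subset[s] or [s]
                for t in targets:
                    rows.append(
                        {"sample": sample_id, "group": group, "panel": t, "proportion": float(frac)}
                    )
            if counts:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                sample_cfg = replace(
                    config,
                    subsets=tuple(
                        (s, int(n)) for s, n in zip(subset_labels, sizes) if n > 0
                    ),
                    seed=sub_seed,
                )
                adata, _ = simulate(sample_cfg, sample_id=sample_id)
                samples[sample_id] = adata

    proportions = pd.DataFrame(rows, columns=["sample", "group", "panel", "proportion"])
    truth = {
        "groups": list(groups),
        "samples_per_group": dict(samples_per_group),
        "shifts": {f"{g}:{s}": v for (g, s), v in (shifts or {}).items()},
        "base_proportions": dict(zip(subset_labels, base.tolist())),
    }
    return StudyResult(samples=samples, proportions=proportions, group_of=group_of, truth=truth)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8")
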