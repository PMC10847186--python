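"""Over-expression-rate (OER) engine: graded cutoffs, binning, classification.

The method scores how *specifically* a marker-gene panel is expressed across
cell populations.  For a panel with designated own population:

1. Per-cell panel score = mean log-normalized expression over the panel's
   high-direction genes.  Within the own population, the highest per-cell
   score is recorded as Q3 and the lowest as Q1.
2. A six-step cutoff ladder is anchored on that range::

       cutoff(k%) = (Q3 - Q1)/10 * (k/10) + Q1,   k in {10, 20, ..., 60}

3. Every evaluated population j (the own population included) is summarized
   by the mean per-cell score s_j and placed in exactly one bin by the
   strictly-greater rule: ">60" if s_j > cutoff(60%), otherwise the interval
   between the highest cutoff it strictly exceeds and the next, and "<10"
   when s_j <= cutoff(10%).
4. OER = 100 * bin count / N, where N (the *total subset number*) is the
   number of populations evaluated; percentages are rounded half-to-even to
   two decimals.  Cumulative counts n_>30 and n_>60 are formed on the raw
   integers before any rounding.
5. Classification:

   * specific  — n_>30 below the 10%-of-N threshold;
   * associate — not specific, and n_>60 at or below the threshold;
   * reference — everything else.

   The default threshold is the integer floor(0.1*N) ("count" mode), which is
   the reading consistent with the published healthy-blood tables (at N = 32
   a panel with n_>30 = 3 is associate, not specific).  The literal
   real-valued 0.1*N is available as ``threshold_mode="exact"``; the two
   differ only when n_>30 equals floor(0.1*N).

A low OER at high cutoffs means other populations rarely reach the panel's
own expression range — the panel is a trustworthy clustering criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal, localcontext
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .matrix import NORMALIZED_FLAG, SUBSET_KEY
from .panels import GenePanel, PanelRegistry

BIN_LABELS = ("<10", "10-20", "20-30", "30-40", "40-50", "50-60", ">60")
CUTOFF_KEYS = (10, 20, 30, 40, 50, 60)

OER_TABLE_COLUMNS = [
    "panel",
    "OER_<10",
    "OER_10-20",
    "OER_20-30",
    "OER_30-40",
    "OER_40-50",
    "OER_50-60",
    "OER_>30",
    "OER_>60",
    "class",
    "n_>30",
    "n_>60",
    "N",
]

__all__ = [
    "BIN_LABELS",
    "CUTOFF_KEYS",
    "OER_TABLE_COLUMNS",
    "PanelScoreSummary",
    "CutoffLadder",
    "OERProfile",
    "PanelClassification",
    "OERResult",
    "panel_cell_scores",
    "summarize_panel",
    "build_cutoffs",
    "assign_bin",
    "bin_subsets",
    "compute_oer",
    "classify_panel",
    "evaluate_all",
    "round_percentage",
    "write_oer_table",
    "read_oer_table",
]


def round_percentage(count: int, total: int) -> float:
    """100*count/total rounded half-to-even to 2 decimals.

    Half-to-even is the only rounding consistent with every printed value of
    the reference tables (e.g. 31/32 -> 96.88, 1/32 -> 3.12, 7/32 -> 21.88,
    3/32 -> 9.38).  Decimal arithmetic avoids binary-float tie artefacts for
    denominators that are not powers of two.
    """
    with localcontext() as ctx:
        ctx.prec = 40
        d = (Decimal(100 * count) / Decimal(total)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)
    return float(d)


# ---------------------------------------------------------------------------
# summaries and cutoffs


@dataclass(frozen=True)
class PanelScoreSummary:
    """Per-population mean panel scores plus the own population's score range."""

    panel: str
    own_subset: str
    scores: dict[str, float]  # population id -> mean per-cell score
    q1: float
    q3: float
    sem: dict[str, float] = field(default_factory=dict)  # reported alongside, unused by binning

    def __post_init__(self) -> None:
        if not np.isfinite(self.q1) or not np.isfinite(self.q3):
            raise ValueError(f"panel {self.panel!r}: non-finite Q1/Q3")
        if self.q1 > self.q3:
            raise ValueError(f"panel {self.panel!r}: Q1 > Q3")
        if self.own_subset not in self.scores:
            raise ValueError(f"panel {self.panel!r}: own population missing from the score universe")
        for pop, s in self.scores.items():
            if not np.isfinite(s):
                raise ValueError(f"panel {self.panel!r}: non-finite score for {pop!r}")


@dataclass(frozen=True)
class CutoffLadder:
    cutoffs: dict[int, float]  # k% -> cutoff value, k in CUTOFF_KEYS
    degenerate: bool = False  # Q1 == Q3: all six cutoffs coincide

    def __getitem__(self, k: int) -> float:
        return self.cutoffs[k]


def panel_cell_scores(adata: AnnData, panel: GenePanel) -> np.ndarray:
    """Per-cell mean of log-normalized expression over high-direction genes."""
    if not adata.uns.get(NORMALIZED_FLAG, False):
        raise ValueError("panel scoring requires a normalized matrix (run qc.normalize)")
    high = panel.high_genes
    if not high:
        raise ValueError(f"panel {panel.name!r} has no high-direction genes")
    var_index = pd.Index(adata.var_names)
    idx = var_index.get_indexer(list(high))
    if (idx < 0).any():
        missing = [g for g, i in zip(high, idx) if i < 0]
        raise ValueError(f"panel {panel.name!r}: genes absent from matrix: {missing}")
    X = adata.X[:, idx]
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    return X.mean(axis=1)


def summarize_panel(
    adata: AnnData,
    panel: GenePanel,
    own_subset: str,
    *,
    populations: Mapping[str, str] | None = None,
    quartile: bool = False,
) -> PanelScoreSummary:
    """Summarize a panel over an evaluation universe of populations.

    ``populations`` maps population id -> subset label; by default each
    distinct subset label is its own population.  Q3/Q1 are the highest and
    lowest per-cell panel score within the own subset (the literal reading);
    ``quartile=True`` switches to the 75th/25th percentiles (linear
    interpolation) for users who prefer the quartile interpretation of the
    Q1/Q3 names.
    """
    labels = adata.obs[SUBSET_KEY].astype(str).to_numpy()
    if own_subset not in set(labels):
        raise ValueError(f"own subset {own_subset!r} absent from labels")
    scores = panel_cell_scores(adata, panel)
    if populations is None:
        populations = {s: s for s in sorted(set(labels))}

    means: dict[str, float] = {}
    sems: dict[str, float] = {}
    own_pop_id = None
    for pop_id, subset in populations.items():
        mask = labels == subset
        if not mask.any():
            raise ValueError(f"population {pop_id!r} (subset {subset!r}) has no cells")
        vals = scores[mask]
        means[pop_id] = float(vals.mean())
        sems[pop_id] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        if subset == own_subset and own_pop_id is None:
            own_pop_id = pop_id
    if own_pop_id is None:
        raise ValueError(f"own subset {own_subset!r} not in the population universe")

    own_vals = scores[labels == own_subset]
    if quartile:
        q1, q3 = (float(q) for q in np.percentile(own_vals, [25, 75]))
    else:
        q1, q3 = float(own_vals.min()), float(own_vals.max())
    return PanelScoreSummary(
        panel=panel.name, own_subset=own_pop_id, scores=means, q1=q1, q3=q3, sem=sems
    )


def build_cutoffs(summary: PanelScoreSummary) -> CutoffLadder:
    """Six graded cutoffs anchored on the own-population score range."""
    q1, q3 = summary.q1, summary.q3
    step = (q3 - q1) / 10.0
    cutoffs = {k: step * (k / 10.0) + q1 for k in CUTOFF_KEYS}
    return CutoffLadder(cutoffs=cutoffs, degenerate=(q3 == q1))


def assign_bin(score: float, ladder: CutoffLadder) -> str:
    """Bin a population mean by the number of cutoffs it strictly exceeds."""
    n_exceeded = sum(score > ladder.cutoffs[k] for k in CUTOFF_KEYS)
    return BIN_LABELS[n_exceeded]


def bin_subsets(
    summary: PanelScoreSummary,
    ladder: CutoffLadder,
    *,
    force_self_top: bool = False,
) -> tuple[dict[str, int], dict[str, str]]:
    """Place every population (own included) in exactly one bin.

    By default the own population is binned by its mean score like any other
    (the mean can fall below cutoff(60%) since mean < max).
    ``force_self_top=True`` pins the own population to ">60" regardless.
    Returns (bin counts, per-population bin assignment).
    """
    counts = {b: 0 for b in BIN_LABELS}
    assignment: dict[str, str] = {}
    for pop, s in summary.scores.items():
        if force_self_top and pop == summary.own_subset:
            b = ">60"
        else:
            b = assign_bin(s, ladder)
        counts[b] += 1
        assignment[pop] = b
    return counts, assignment


# ---------------------------------------------------------------------------
# OER profiles and classification


@dataclass(frozen=True)
class OERProfile:
    """Bin counts and OER percentages for one panel over N populations."""

    panel: str
    n_total: int
    counts: dict[str, int]  # per BIN_LABELS
    n_gt30: int
    n_gt60: int
    oer: dict[str, float]  # per BIN_LABELS, percentages
    oer_gt30: float
    oer_gt60: float
    degenerate: bool = False
    assignments: dict[str, str] = field(default_factory=dict)


def compute_oer(
    panel: str,
    counts: Mapping[str, int] | Sequence[int],
    n_total: int,
    *,
    strict: bool = True,
    degenerate: bool = False,
    assignments: Mapping[str, str] | None = None,
) -> OERProfile:
    """Turn bin counts into an OER profile.

    ``strict`` (default) demands the seven bin counts sum exactly to
    ``n_total``; ``strict=False`` tolerates a shortfall, which is needed to
    audit published tables whose printed rows leave a population unaccounted.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not isinstance(counts, Mapping):
        if len(counts) != len(BIN_LABELS):
            raise ValueError(f"expected {len(BIN_LABELS)} bin counts, got {len(counts)}")
        counts = dict(zip(BIN_LABELS, counts))
    counts = {b: int(counts.get(b, 0)) for b in BIN_LABELS}
    if any(c < 0 for c in counts.values()):
        raise ValueError("bin counts must be non-negative")
    total = sum(counts.values())
    if strict and total != n_total:
        raise ValueError(f"panel {panel!r}: bin counts sum to {total}, expected N={n_total}")
    if total > n_total:
        raise ValueError(f"panel {panel!r}: bin counts sum to {total} > N={n_total}")

    n_gt30 = sum(counts[b] for b in ("30-40", "40-50", "50-60", ">60"))
    n_gt60 = counts[">60"]
    oer = {b: round_percentage(counts[b], n_total) for b in BIN_LABELS}
    return OERProfile(
        panel=panel,
        n_total=n_total,
        counts=counts,
        n_gt30=n_gt30,
        n_gt60=n_gt60,
        oer=oer,
        oer_gt30=round_percentage(n_gt30, n_total),
        oer_gt60=round_percentage(n_gt60, n_total),
        degenerate=degenerate,
        assignments=dict(assignments or {}),
    )


@dataclass(frozen=True)
class PanelClassification:
    panel: str
    label: str  # specific | associate | reference
    n_gt30: int
    n_gt60: int
    n_total: int
    threshold: float  # exact 0.1 * N, never rounded
    threshold_count: int  # floor(0.1 * N), used in "count" mode
    mode: str = "count"


def classify_panel(profile: OERProfile, *, threshold_mode: str = "count") -> PanelClassification:
    """Three-way specificity call from cumulative subset numbers.

    ``threshold_mode="count"`` (default) compares against floor(0.1*N);
    ``"exact"`` uses the real-valued 0.1*N.  See the module docstring for why
    "count" is the default.
    """
    if threshold_mode not in ("count", "exact"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    n = profile.n_total
    exact = n / 10.0
    cut: float = n // 10 if threshold_mode == "count" else exact
    if profile.n_gt30 < cut:
        label = "specific"
    elif profile.n_gt60 <= cut:
        label = "associate"
    else:
        label = "reference"
    return PanelClassification(
        panel=profile.panel,
        label=label,
        n_gt30=profile.n_gt30,
        n_gt60=profile.n_gt60,
        n_total=n,
        threshold=exact,
        threshold_count=n // 10,
        mode=threshold_mode,
    )


# ---------------------------------------------------------------------------
# whole-registry evaluation


@dataclass
class OERResult:
    profiles: dict[str, OERProfile]
    classifications: dict[str, PanelClassification]
    summaries: dict[str, PanelScoreSummary]
    own_subsets: dict[str, str]  # panel -> subset label of its own population
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, prof in self.profiles.items():
            cls = self.classifications[name]
            rows.append(
                {
                    "panel": name,
                    "OER_<10": prof.oer["<10"],
                    "OER_10-20": prof.oer["10-20"],
                    "OER_20-30": prof.oer["20-30"],
                    "OER_30-40": prof.oer["30-40"],
                    "OER_40-50": prof.oer["40-50"],
                    "OER_50-60": prof.oer["50-60"],
                    "OER_>30": prof.oer_gt30,
                    "OER_>60": prof.oer_gt60,
                    "class": cls.label,
                    "n_>30": prof.n_gt30,
                    "n_>60": prof.n_gt60,
                    "N": prof.n_total,
                }
            )
        return pd.DataFrame(rows, columns=OER_TABLE_COLUMNS).sort_values("panel").reset_index(drop=True)


def evaluate_all(
    adata: AnnData,
    registry: PanelRegistry,
    detections: pd.DataFrame,
    *,
    quartile: bool = False,
    force_self_top: bool = False,
    threshold_mode: str = "count",
) -> OERResult:
    """OER profile + classification for every detected panel.

    The evaluation universe is the set of detected panels: each detected
    panel contributes one population, the cells of the subset where its
    positivity is highest (its *own* subset).  N — the total subset number —
    is therefore the number of detected panels and is identical across all
    profiles of one run.  Output is invariant to panel input order (panels
    are processed in sorted-name order).
    """
    hits = detections[detections["detected"]]
    if hits.empty:
        raise ValueError("zero detected panels; nothing to evaluate")

    own_subsets: dict[str, str] = {}
    for name in sorted(hits["panel"].unique()):
        if name not in registry:
            raise KeyError(f"detected panel {name!r} missing from registry")
        sub = hits[hits["panel"] == name].sort_values(["positivity", "subset"], ascending=[False, True])
        own_subsets[name] = str(sub.iloc[0]["subset"])

    populations = dict(own_subsets)  # population id == panel name
    n_total = len(populations)

    profiles: dict[str, OERProfile] = {}
    classifications: dict[str, PanelClassification] = {}
    summaries: dict[str, PanelScoreSummary] = {}
    for name, own in own_subsets.items():
        summary = summarize_panel(
            adata, registry[name], own, populations=populations, quartile=quartile
        )
        # own population must be the panel's own entry, not another panel
        # sharing the same subset label
        summary = PanelScoreSummary(
            panel=summary.panel,
            own_subset=name,
            scores=summary.scores,
            q1=summary.q1,
            q3=summary.q3,
            sem=summary.sem,
        )
        ladder = build_cutoffs(summary)
        counts, assignment = bin_subsets(summary, ladder, force_self_top=force_self_top)
        prof = compute_oer(
            name, counts, n_total, degenerate=ladder.degenerate, assignments=assignment
        )
        profiles[name] = prof
        classifications[name] = classify_panel(prof, threshold_mode=threshold_mode)
        summaries[name] = summary
    return OERResult(
        profiles=profiles,
        classifications=classifications,
        summaries=summaries,
        own_subsets=own_subsets,
        n_total=n_total,
    )


# ---------------------------------------------------------------------------
# table I/O (Tables 1-3 layout)


def write_oer_table(result_or_frame, path: str | Path) -> Path:
    frame = result_or_frame.to_frame() if isinstance(result_or_frame, OERResult) else result_or_frame
    frame = frame[OER_TABLE_COLUMNS]
    frame.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_oer_table(path: str | Path) -> list[tuple[OERProfile, str | None]]:
    """Read an OER table TSV back into profiles for classification-only runs.

    Integer columns (n_>30, n_>60, N) are used when present; otherwise bin
    counts are reconstructed from the percentages as round(OER * N / 100).
    Rows whose reconstructed counts do not sum to N (possible in published
    tables) yield non-strict profiles.
    """
    frame = pd.read_csv(path, sep="\t")
    return frame_to_profiles(frame)


def frame_to_profiles(
    frame: pd.DataFrame, *, default_n: int | None = None
) -> list[tuple[OERProfile, str | None]]:
    out: list[tuple[OERProfile, str | None]] = []
    interval_cols = ["OER_<10", "OER_10-20", "OER_20-30", "OER_30-40", "OER_40-50", "OER_50-60"]
    for _, row in frame.iterrows():
        n_total = int(row["N"]) if "N" in frame.columns and pd.notna(row.get("N")) else default_n
        if n_total is None:
            raise ValueError("OER table has no N column and no default_n was given")
        counts = [int(round(float(row[c]) * n_total / 100.0)) for c in interval_cols]
        if "n_>60" in frame.columns and pd.notna(row.get("n_>60")):
            n_gt60 = int(row["n_>60"])
        else:
            n_gt60 = int(round(float(row["OER_>60"]) * n_total / 100.0))
        counts.append(n_gt60)
        strict = sum(counts) == n_total
        prof = compute_oer(str(row["panel"]), counts, n_total, strict=strict)
        label = str(row["class"]) if "class" in frame.columns and pd.notna(row.get("class")) else None
        out.append((prof, label))
    return out
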