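"""End-to-end pipeline, run configuration, and publication-style rendering."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from anndata import AnnData

from .identify import compare_groups, detect_panels, resolve_multi_assignment
from .matrix import SAMPLE_KEY, SUBSET_KEY, read_labeled
from .oer import OERResult, classify_panel, evaluate_all, read_oer_table, write_oer_table
from .panels import load_panels, restrict_to_matrix
from .qc import normalize, qc_filter, reference_cluster

logger = logging.getLogger("panelscope")

CLASS_COLORS = {"specific": "blue", "associate": "pink", "reference": "red"}

__all__ = ["RunConfig", "RunBundle", "run_pipeline", "classify_only", "render_oer_table", "CLASS_COLORS"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML round-trips losslessly."""

    input_dir: str | None = None  # labeled-matrix directory (mtx or tsv layout)
    panels_file: str | None = None
    hierarchy_file: str | None = None
    output_dir: str = "panelscope_out"
    # thresholds
    positivity_threshold: float = 0.10
    positive_min: float = 0.0
    min_genes: int = 500
    max_genes: int = 7000
    max_mito_frac: float = 0.20
    mito_prefix: str = "MT-"
    scale_total: float = 1e4
    # OER options
    quartile_mode: bool = False
    force_self_top: bool = False
    threshold_mode: str = "count"
    # labels fallback
    cluster_k: int | None = None  # run the reference clusterer when labels are absent
    # group comparison: list of [group_a, group_b]
    comparisons: list[list[str]] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 <= self.positivity_threshold <= 1:
            raise ValueError("positivity_threshold must be in [0, 1]")
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must be in [0, 1]")
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        if self.threshold_mode not in ("count", "exact"):
            raise ValueError("threshold_mode must be 'count' or 'exact'")
        for path in (self.input_dir, self.panels_file, self.hierarchy_file):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")


@dataclass
class RunBundle:
    output_dir: Path
    qc_report: pd.DataFrame
    detections: pd.DataFrame
    oer: OERResult
    assignments: dict[str, str]
    proportions: pd.DataFrame
    comparisons: dict[str, pd.DataFrame]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def panel_proportions(adata: AnnData, assignments: dict[str, str]) -> pd.DataFrame:
    """Per-sample fraction of cells belonging to each panel's assigned subsets.

    Assignment is exclusive (one panel per subset), so fractions within a
    sample sum to <= 1; subsets with no assigned panel contribute nothing.
    """
    obs = adata.obs[[SUBSET_KEY, SAMPLE_KEY]].astype(str)
    rows = []
    for sample, sub in obs.groupby(SAMPLE_KEY, sort=True):
        total = len(sub)
        counts: dict[str, int] = {}
        for subset, n in sub[SUBSET_KEY].value_counts().items():
            panel = assignments.get(str(subset))
            if panel is not None:
                counts[panel] = counts.get(panel, 0) + int(n)
        for panel, n in sorted(counts.items()):
            rows.append({"sample": sample, "panel": panel, "proportion": n / total})
    return pd.DataFrame(rows, columns=["sample", "panel", "proportion"])


def run_pipeline(config: RunConfig, adata: AnnData | None = None, groups: dict[str, str] | None = None) -> RunBundle:
    """QC -> normalize -> detect -> OER/classify -> resolve -> proportions.

    ``adata`` may be passed directly (e.g. fresh from the simulator);
    otherwise ``config.input_dir`` is read.  ``groups`` maps sample id ->
    group label for between-group comparisons.  Deterministic given the
    config seed; every stage's intermediate is written under the output
    directory.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    hashes: dict[str, str] = {}

    if adata is None:
        if config.input_dir is None:
            raise ValueError("either pass a matrix or set input_dir")
        adata = read_labeled(config.input_dir)
        for f in Path(config.input_dir).iterdir():
            if f.is_file():
                hashes[f.name] = _sha256(f)
    timings["load"] = time.time() - t0

    if config.panels_file is None:
        raise ValueError("panels_file is required")
    registry = load_panels(config.panels_file, config.hierarchy_file)
    hashes[Path(config.panels_file).name] = _sha256(Path(config.panels_file))

    t = time.time()
    adata, qc_report = qc_filter(
        adata,
        min_genes=config.min_genes,
        max_genes=config.max_genes,
        max_mito_frac=config.max_mito_frac,
        mito_prefix=config.mito_prefix,
    )
    adata = normalize(adata, scale_total=config.scale_total)
    timings["qc_normalize"] = time.time() - t
    qc_report.to_csv(outdir / "qc_exclusions.tsv", sep="\t", index=False)
    (outdir / "qc_report.json").write_text(
        json.dumps(
            {
                "n_cells_kept": int(adata.n_obs),
                "n_cells_removed": int(len(qc_report)),
                "removed_by_reason": qc_report["reason"].value_counts().to_dict(),
            },
            indent=2,
        ),
        encoding="utf-8",
    )

    if config.cluster_k is not None:
        adata.obs[SUBSET_KEY] = reference_cluster(adata, config.cluster_k, config.seed).values

    registry, restrict_report = restrict_to_matrix(registry, set(adata.var_names))
    restrict_report.to_csv(outdir / "panel_restriction.tsv", sep="\t", index=False)

    t = time.time()
    detections = detect_panels(
        adata, registry, config.positivity_threshold, config.positive_min
    )
    detections.to_csv(outdir / "detections.tsv", sep="\t", index=False)
    timings["detect"] = time.time() - t

    t = time.time()
    result = evaluate_all(
        adata,
        registry,
        detections,
        quartile=config.quartile_mode,
        force_self_top=config.force_self_top,
        threshold_mode=config.threshold_mode,
    )
    write_oer_table(result, outdir / "oer_table.tsv")
    timings["oer"] = time.time() - t

    assignments = resolve_multi_assignment(detections, result.profiles)
    pd.Series(assignments, name="panel").rename_axis("subset").to_csv(
        outdir / "subset_assignments.tsv", sep="\t"
    )
    proportions = panel_proportions(adata, assignments)
    if groups:
        proportions["group"] = proportions["sample"].map(groups)
    proportions.to_csv(outdir / "proportions.tsv", sep="\t", index=False)

    comparisons: dict[str, pd.DataFrame] = {}
    for pair in config.comparisons:
        a, b = pair
        frame = compare_groups(proportions, a, b)
        key = f"{a}_vs_{b}"
        frame.to_csv(outdir / f"comparison_{key}.tsv", sep="\t", index=False)
        comparisons[key] = frame

    (outdir / "run_log.json").write_text(
        json.dumps(
            {"timings_s": timings, "input_sha256": hashes, "seed": config.seed, "n_total": result.n_total},
            indent=2,
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    logger.info("pipeline finished: %d panels over N=%d populations", len(result.profiles), result.n_total)
    return RunBundle(
        output_dir=outdir,
        qc_report=qc_report,
        detections=detections,
        oer=result,
        assignments=assignments,
        proportions=proportions,
        comparisons=comparisons,
    )


def classify_only(oer_table: str | Path, *, threshold_mode: str = "count") -> pd.DataFrame:
    """Re-classify panels from a previously written OER table."""
    rows = []
    for profile, _ in read_oer_table(oer_table):
        cls = classify_panel(profile, threshold_mode=threshold_mode)
        rows.append(
            {
                "panel": cls.panel,
                "class": cls.label,
                "n_>30": cls.n_gt30,
                "n_>60": cls.n_gt60,
                "N": cls.n_total,
            }
        )
    return pd.DataFrame(rows)


def _fmt_pct(v: float) -> str:
    """Render a percentage the way the reference tables print it (96.88, 12.5, 0)."""
    s = f"{v:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def render_oer_table(result_or_frame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Format an OER table for publication and emit stacked-bar plot data.

    Returns (string-formatted table, long-format plot data with the class
    color key: specific/associate/reference as blue/pink/red).
    """
    frame = (
        result_or_frame.to_frame() if isinstance(result_or_frame, OERResult) else result_or_frame.copy()
    )
    if frame.empty:
        raise ValueError("empty OER table")
    pct_cols = [c for c in frame.columns if c.startswith("OER_")]
    rendered = frame.copy()
    for c in pct_cols:
        rendered[c] = rendered[c].map(_fmt_pct)
    plot_rows = []
    for _, row in frame.iterrows():
        for c in pct_cols:
            plot_rows.append(
                {
                    "panel": row["panel"],
                    "bin": c.removeprefix("OER_"),
                    "oer": float(row[c]),
                    "class": row.get("class", ""),
                    "color": CLASS_COLORS.get(row.get("class", ""), "gray"),
                }
            )
    return rendered, pd.DataFrame(plot_rows)


def plot_oer_stacked(plot_data: pd.DataFrame, path: str | Path) -> Path:
    """Stacked per-panel OER bars (interval bins only), panel names colored
    by class using the specific/associate/reference = blue/pink/red key."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    interval = plot_data[plot_data["bin"] != ">30"]  # intervals + >60 sum to 100
    pivot = interval.pivot(index="panel", columns="bin", values="oer")
    order = ["<10", "10-20", "20-30", "30-40", "40-50", "50-60", ">60"]
    pivot = pivot[[c for c in order if c in pivot.columns]]
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(pivot)), 4))
    pivot.plot(kind="bar", stacked=True, ax=ax, colormap="viridis", width=0.85)
    colors = plot_data.drop_duplicates("panel").set_index("panel")["color"]
    for tick in ax.get_xticklabels():
        tick.set_color(colors.get(tick.get_text(), "gray"))
    ax.set_ylabel("OER (%)")
    ax.legend(title="cutoff bin", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
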