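"""Gene-panel registry: GMT parsing, hierarchy validation, gene-universe restriction.

A *gene panel* is a named set of marker genes published to define a cell
subpopulation (here: neutrophil subsets such as ``Neu_c1_IL1B`` or
``CD74_Neu``).  Panels may carry per-gene direction flags: a token written
``GENE(low)`` marks a negative/low marker.  Low-direction genes are excluded
from the all-markers-positive rule and from panel scoring by default, because
there is no established convention for folding negative markers into a mean
expression score; direction handling is configurable downstream.

Panels are read and written in GMT format (tab-separated: name, description,
genes...), the de-facto standard for gene-set collections.  An optional
two-column TSV (parent, child) declares a subset hierarchy, which must form a
forest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "GenePanel",
    "PanelHierarchy",
    "PanelRegistry",
    "load_panels",
    "write_panels",
    "restrict_to_matrix",
]

_DIRECTION_RE = re.compile(r"^(?P<gene>.+?)\((?P<direction>high|low)\)$", re.IGNORECASE)


def parse_gene_token(token: str) -> tuple[str, str]:
    """Split a GMT gene token into (symbol, direction).

    ``"IL1B" -> ("IL1B", "high")``; ``"OASL(low)" -> ("OASL", "low")``.
    """
    token = token.strip()
    m = _DIRECTION_RE.match(token)
    if m:
        return m.group("gene").strip(), m.group("direction").lower()
    return token, "high"


@dataclass(frozen=True)
class GenePanel:
    """A named marker-gene set with optional per-gene direction flags."""

    name: str
    genes: tuple[str, ...]
    directions: tuple[str, ...] = ()
    description: str = ""
    source_tier: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("panel name must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(f"panel {self.name!r}: gene list is empty")
        if not self.directions:
            object.__setattr__(self, "directions", ("high",) * len(self.genes))
        if len(self.directions) != len(self.genes):
            raise ValueError(f"panel {self.name!r}: directions do not align with genes")
        if any(d not in ("high", "low") for d in self.directions):
            raise ValueError(f"panel {self.name!r}: directions must be 'high' or 'low'")
        seen: set[str] = set()
        for g in self.genes:
            if not g:
                raise ValueError(f"panel {self.name!r}: empty gene symbol")
            if g in seen:
                raise ValueError(f"panel {self.name!r}: duplicate gene symbol {g!r}")
            seen.add(g)

    @property
    def high_genes(self) -> tuple[str, ...]:
        return tuple(g for g, d in zip(self.genes, self.directions) if d == "high")

    @property
    def low_genes(self) -> tuple[str, ...]:
        return tuple(g for g, d in zip(self.genes, self.directions) if d == "low")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PanelHierarchy:
    """Parent -> child edges among panel names; must form a forest."""

    edges: tuple[tuple[str, str], ...] = ()
    detected_flags: dict[str, dict[str, bool]] = field(default_factory=dict)

    def validate(self, panel_names: Iterable[str]) -> None:
        names = set(panel_names)
        g = nx.DiGraph()
        g.add_nodes_from(names)
        for parent, child in self.edges:
            for endpoint in (parent, child):
                if endpoint not in names:
                    raise ValueError(f"hierarchy references unregistered panel {endpoint!r}")
            g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"hierarchy contains a cycle: {cycle}")
        bad = [n for n, deg in g.in_degree() if deg > 1]
        if bad:
            raise ValueError(f"hierarchy is not a forest; multiple parents for: {bad}")

    def children(self, name: str) -> list[str]:
        return [c for p, c in self.edges if p == name]

    def to_dot(self) -> str:
        lines = ["digraph panel_hierarchy {"]
        for parent, child in self.edges:
            lines.append(f'  "{parent}" -> "{child}";')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class PanelRegistry:
    """Ordered collection of uniquely named panels plus optional hierarchy.

    ``undetectable`` holds panels that lost every gene during restriction to a
    matrix's gene universe; they are kept for reporting but excluded from
    scoring.
    """

    panels: dict[str, GenePanel] = field(default_factory=dict)
    hierarchy: PanelHierarchy | None = None
    undetectable: dict[str, GenePanel] = field(default_factory=dict)

    def add(self, panel: GenePanel) -> None:
        if panel.name in self.panels or panel.name in self.undetectable:
            raise ValueError(f"duplicate panel name {panel.name!r}")
        self.panels[panel.name] = panel

    def __iter__(self) -> Iterator[GenePanel]:
        return iter(self.panels.values())

    def __len__(self) -> int:
        return len(self.panels)

    def __contains__(self, name: str) -> bool:
        return name in self.panels

    def __getitem__(self, name: str) -> GenePanel:
        return self.panels[name]

    @property
    def names(self) -> list[str]:
        return list(self.panels)

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for p in self:
            out.update(p.genes)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PanelRegistry):
            return NotImplemented
        return self.panels == other.panels and (
            (self.hierarchy is None) == (other.hierarchy is None)
            and (self.hierarchy is None or self.hierarchy.edges == other.hierarchy.edges)
        )


def _read_hierarchy(path: Path) -> PanelHierarchy:
    edges: list[tuple[str, str]] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"hierarchy rows need exactly 2 tab-separated fields, got: {raw!r}")
        edges.append((fields[0].strip(), fields[1].strip()))
    return PanelHierarchy(edges=tuple(edges))


def load_panels(
    geneset_file: str | Path,
    hierarchy_file: str | Path | None = None,
    *,
    case_insensitive: bool = False,
) -> PanelRegistry:
    """Read a GMT gene-set file (and optional hierarchy TSV) into a registry.

    Each GMT row must have >= 3 tab-separated fields: name, description,
    then one or more gene tokens.  Gene symbols are whitespace-stripped and,
    by default, matched case-sensitively (``case_insensitive=True`` upper-cases
    symbols at parse time; panel *names* are never case-folded because
    published panel names mix conventions).
    """
    path = Path(geneset_file)
    registry = PanelRegistry()
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path.name}:{lineno}: GMT rows need >=3 tab-separated fields "
                f"(name, description, genes...)"
            )
        name = fields[0].strip()
        description = fields[1].strip()
        genes: list[str] = []
        directions: list[str] = []
        for token in fields[2:]:
            if not token.strip():
                continue
            gene, direction = parse_gene_token(token)
            if case_insensitive:
                gene = gene.upper()
            genes.append(gene)
            directions.append(direction)
        if not genes:
            raise ValueError(f"{path.name}:{lineno}: panel {name!r} has an empty gene list")
        registry.add(
            GenePanel(name=name, genes=tuple(genes), directions=tuple(directions), description=description)
        )
    if hierarchy_file is not None:
        hierarchy = _read_hierarchy(Path(hierarchy_file))
        hierarchy.validate(registry.names)
        registry.hierarchy = hierarchy
    return registry


def write_panels(registry: PanelRegistry, path: str | Path) -> None:
    """Write a registry back to GMT; round-trips with :func:`load_panels`."""
    lines = []
    for panel in registry:
        tokens = [
            g if d == "high" else f"{g}(low)" for g, d in zip(panel.genes, panel.directions)
        ]
        lines.append("\t".join([panel.name, panel.description or "-", *tokens]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def restrict_to_matrix(
    registry: PanelRegistry,
    gene_universe: Iterable[str],
    *,
    case_insensitive: bool = False,
) -> tuple[PanelRegistry, pd.DataFrame]:
    """Intersect every panel with a matrix's gene universe.

    Returns the restricted registry plus a per-panel report of dropped
    symbols.  Panels that lose all genes are flagged undetectable and moved
    out of the scoring set.  Idempotent: restricting an already restricted
    registry with the same universe is a no-op.
    """
    universe = set(gene_universe)
    if not universe:
        raise ValueError("gene_universe must be non-empty")
    lookup = {g.upper(): g for g in universe} if case_insensitive else None

    out = PanelRegistry(hierarchy=registry.hierarchy)
    rows = []
    for panel in registry:
        kept_genes: list[str] = []
        kept_dirs: list[str] = []
        dropped: list[str] = []
        for g, d in zip(panel.genes, panel.directions):
            if case_insensitive:
                match = lookup.get(g.upper())
                if match is not None:
                    kept_genes.append(match)
                    kept_dirs.append(d)
                else:
                    dropped.append(g)
            elif g in universe:
                kept_genes.append(g)
                kept_dirs.append(d)
            else:
                dropped.append(g)
        undetectable = len(kept_genes) == 0
        rows.append(
            {
                "panel": panel.name,
                "n_genes": len(panel),
                "n_kept": len(kept_genes),
                "dropped": ",".join(dropped),
                "undetectable": undetectable,
            }
        )
        if undetectable:
            out.undetectable[panel.name] = panel
        else:
            out.add(
                GenePanel(
                    name=panel.name,
                    genes=tuple(kept_genes),
                    directions=tuple(kept_dirs),
                    description=panel.description,
                    source_tier=panel.source_tier,
                )
            )
    report = pd.DataFrame(rows, columns=["panel", "n_genes", "n_kept", "dropped", "undetectable"])
    return out, report
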