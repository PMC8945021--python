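"""Core data types and file I/O for enrichment analysis of regulatory elements.

The on-disk formats are deliberately plain: GMT (MSigDB dialect) for
annotation databases, two-column TSV for regulator→target interactomes,
CpG→gene maps and gene-length tables, and one-ID-per-line text for input
lists and custom background universes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "AnnotationDatabase",
    "Interactome",
    "InputList",
    "Universe",
    "GeneCovariateTable",
    "ParseError",
    "read_gmt",
    "write_gmt",
    "read_interactome",
    "read_id_list",
    "read_covariate_table",
    "resolve_universe",
    "write_results",
    "RESULT_COLUMNS",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


@dataclass(frozen=True)
class AnnotationDatabase:
    """A term → element-set catalogue (GO-, KEGG-, TAM-like).

    ``element_kind`` is ``"gene"`` for ordinary gene-annotation sources and
    ``"mirna"`` for direct miRNA annotations or gene databases transformed
    into miRNA space.
    """

    source_name: str
    terms: Mapping[str, tuple[str, frozenset[str]]]  # term_id -> (name, elements)
    element_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.element_kind not in ("gene", "mirna"):
            raise ValueError(f"unknown element_kind {self.element_kind!r}")
        for tid, (_, elems) in self.terms.items():
            if not elems:
                raise ValueError(f"term {tid!r} has no elements")

    def annotated_universe(self) -> frozenset[str]:
        """Union of all term element sets — the 'annotated' background."""
        out: set[str] = set()
        for _, elems in self.terms.values():
            out |= elems
        return frozenset(out)

    def term_elements(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def term_name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class Interactome:
    """Regulator → target-gene edge set (miRNA–gene, TF–gene or CpG–gene)."""

    kind: str  # mirna | tf | cpg
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in ("mirna", "tf", "cpg"):
            raise ValueError(f"unknown interactome kind {self.kind!r}")

    def regulators(self) -> frozenset[str]:
        return frozenset(r for r, _ in self.edges)

    def targets(self) -> frozenset[str]:
        return frozenset(g for _, g in self.edges)

    def targets_of(self, regulator: str) -> frozenset[str]:
        return frozenset(g for r, g in self.edges if r == regulator)

    def regulator_count(self) -> dict[str, int]:
        """Number of distinct regulators per target gene (the bias covariate)."""
        counts: dict[str, int] = {}
        for _, g in self.edges:
            counts[g] = counts.get(g, 0) + 1
        return counts

    def adjacency(self) -> dict[str, frozenset[str]]:
        """regulator -> set of target genes, materialised once."""
        adj: dict[str, set[str]] = {}
        for r, g in self.edges:
            adj.setdefault(r, set()).add(g)
        return {r: frozenset(gs) for r, gs in adj.items()}


@dataclass(frozen=True)
class InputList:
    """A user input list after de-duplication and recognition against a
    reference namespace (interactome regulators, database elements, ...)."""

    raw_ids: tuple[str, ...]
    input_kind: str  # gene | mirna | tf | cpg
    mapped: frozenset[str]
    unmapped: tuple[str, ...]
    n_duplicates: int = 0

    @staticmethod
    def from_ids(raw_ids: Sequence[str], input_kind: str, known: Iterable[str]) -> "InputList":
        known = frozenset(known)
        seen: dict[str, None] = {}
        for rid in raw_ids:
            seen.setdefault(rid)
        distinct = list(seen)
        mapped = frozenset(i for i in distinct if i in known)
        unmapped = tuple(i for i in distinct if i not in known)
        return InputList(
            raw_ids=tuple(raw_ids),
            input_kind=input_kind,
            mapped=mapped,
            unmapped=unmapped,
            n_duplicates=len(raw_ids) - len(distinct),
        )


@dataclass(frozen=True)
class Universe:
    """Background element set; M of the contingency counts is its size."""

    scope: str  # annotated | whole | custom
    elements: frozenset[str]

    def __post_init__(self) -> None:
        if self.scope not in ("annotated", "whole", "custom"):
            raise ValueError(f"unknown universe scope {self.scope!r}")
        if not self.elements:
            raise ValueError("empty background")

    @property
    def M(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class GeneCovariateTable:
    """Per-gene nonnegative bias covariate: length in bp, CpG probe count,
    or number of regulators targeting the gene."""

    values: Mapping[str, float]
    name: str = "covariate"

    def __post_init__(self) -> None:
        for g, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"covariate for {g!r} must be finite and >= 0, got {v}")

    def get(self, gene: str) -> float:
        return float(self.values.get(gene, 0.0))


# ---------------------------------------------------------------------------
# readers / writers


def read_gmt(path: str | Path, element_kind: str = "gene", source_name: Optional[str] = None) -> AnnotationDatabase:
    """Read a GMT file: ``term_id<TAB>description<TAB>elem1<TAB>elem2...``.

    Empty element fields are dropped and duplicates within a line collapsed.
    Lines with fewer than three fields raise :class:`ParseError`.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}")
            term_id, desc = fields[0], fields[1]
            elems = frozenset(e for e in fields[2:] if e.strip())
            if not elems:
                raise ParseError(f"{path.name}:{lineno}: term {term_id!r} has no elements")
            terms[term_id] = (desc, elems)
    if not terms:
        raise ParseError(f"{path.name}: empty GMT file")
    return AnnotationDatabase(source_name=source_name or path.stem, terms=terms, element_kind=element_kind)


def write_gmt(db: AnnotationDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(db.terms):
            name, elems = db.terms[tid]
            fh.write("\t".join([tid, name, *sorted(elems)]) + "\n")


def read_interactome(path: str | Path, kind: str) -> Interactome:
    """Read a two-column TSV of (regulator, target gene) pairs.

    Header lines starting with ``#`` are skipped; duplicate pairs collapse.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path.name}:{lineno}: expected exactly 2 tab-separated fields, got {len(fields)}")
            reg, tgt = fields[0].strip(), fields[1].strip()
            if not reg or not tgt:
                raise ParseError(f"{path.name}:{lineno}: empty identifier")
            edges.add((reg, tgt))
    if not edges:
        raise ParseError(f"{path.name}: interactome has zero edges")
    return Interactome(kind=kind, edges=frozenset(edges))


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored.
    Order and duplicates preserved (de-duplication is InputList's job)."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_covariate_table(path: str | Path, name: str = "covariate") -> GeneCovariateTable:
    """Two-column TSV gene<TAB>value (e.g. gene length in bp)."""
    path = Path(path)
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path.name}:{lineno}: expected 2 fields, got {len(fields)}")
            try:
                values[fields[0]] = float(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric value {fields[1]!r}") from exc
    return GeneCovariateTable(values=values, name=name)


def resolve_universe(
    scope: str,
    dbs: Sequence[AnnotationDatabase] = (),
    catalogue: Optional[Iterable[str]] = None,
    custom: Optional[Iterable[str]] = None,
) -> Universe:
    """Build the background set.

    annotated — union of the selected databases' annotated universes;
    whole     — the full measurable catalogue (supplied as a file);
    custom    — a user-provided set.
    """
    if scope == "annotated":
        elems: set[str] = set()
        for db in dbs:
            elems |= db.annotated_universe()
    elif scope == "whole":
        if catalogue is None:
            raise ValueError("scope='whole' requires a catalogue")
        elems = set(catalogue)
    elif scope == "custom":
        if not custom:
            raise ValueError("scope='custom' requires a nonempty custom set")
        elems = set(custom)
    else:
        raise ValueError(f"unknown universe scope {scope!r}")
    if not elems:
        raise ValueError("empty background")
    return Universe(scope=scope, elements=frozenset(elems))


RESULT_COLUMNS = [
    "term_id",
    "term_name",
    "source",
    "x",
    "n",
    "N",
    "M",
    "w",
    "pvalue",
    "padj",
    "rel_enrichment",
    "input_elements",
    "support_genes",
]


def write_results(rows: Sequence["object"], path: str | Path, extra_columns: Sequence[str] = ()) -> None:
    """Write enrichment rows as TSV in the canonical sort order.

    Rows must already be sorted (padj asc, then pvalue, then term_id); the
    writer re-asserts the order so equal inputs give byte-identical files.
    `w` is left empty for plain hypergeometric runs.
    """
    cols = [*RESULT_COLUMNS, *extra_columns]
    ordered = sorted(rows, key=lambda r: (r.padj, r.pvalue, r.term_id))
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in ordered:
            rec = {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "source": r.source,
                "x": str(r.counts.x),
                "n": str(r.counts.n),
                "N": str(r.counts.N),
                "M": str(r.counts.M),
                "w": "" if r.w is None else f"{r.w:.6g}",
                "pvalue": f"{r.pvalue:.6g}",
                "padj": f"{r.padj:.6g}",
                "rel_enrichment": f"{r.rel_enrichment:.6g}",
                "input_elements": ",".join(sorted(r.input_elements)),
                "support_genes": ",".join(sorted(r.support)),
            }
            for c in extra_columns:
                rec[c] = str(getattr(r, c, ""))
            fh.write("\t".join(rec[c] for c in cols) + "\n")
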