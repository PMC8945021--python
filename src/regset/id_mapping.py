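"""Identifier conversion and projection.

Covers the three mapping steps an analysis of regulatory elements needs:
precursor↔mature miRNA expansion, regulator→target-gene projection, and the
transformation of gene-based annotation databases into miRNA space (each
term rewritten as the set of miRNAs targeting at least one of its genes,
each miRNA counted once per term however many genes it targets).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .data_model import AnnotationDatabase, InputList, Interactome, ParseError, Universe

__all__ = [
    "MirnaMap",
    "TargetProjection",
    "read_mirna_map",
    "convert_mirna_ids",
    "project_to_targets",
    "transform_db_to_mirnas",
    "qc_report",
]


@dataclass(frozen=True)
class MirnaMap:
    """Bidirectional precursor (hairpin, 'mir') ↔ mature ('miR') map."""

    precursor_to_mature: Mapping[str, frozenset[str]]
    mature_to_precursor: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for p, ms in self.precursor_to_mature.items():
            for m in ms:
                if p not in self.mature_to_precursor.get(m, frozenset()):
                    raise ValueError(f"inconsistent map: {m!r} missing inverse of {p!r}")
        for m, ps in self.mature_to_precursor.items():
            for p in ps:
                if m not in self.precursor_to_mature.get(p, frozenset()):
                    raise ValueError(f"inconsistent map: {p!r} missing inverse of {m!r}")

    @staticmethod
    def from_pairs(pairs: Sequence[tuple[str, str]]) -> "MirnaMap":
        p2m: dict[str, set[str]] = {}
        m2p: dict[str, set[str]] = {}
        for p, m in pairs:
            p2m.setdefault(p, set()).add(m)
            m2p.setdefault(m, set()).add(p)
        return MirnaMap(
            precursor_to_mature={p: frozenset(v) for p, v in p2m.items()},
            mature_to_precursor={m: frozenset(v) for m, v in m2p.items()},
        )


@dataclass(frozen=True)
class TargetProjection:
    """Target genes of an input regulator list, with provenance."""

    target_genes: frozenset[str]
    contributing: Mapping[str, frozenset[str]]  # gene -> input regulators hitting it
    regulators_without_targets: tuple[str, ...] = ()


def read_mirna_map(path: str | Path) -> MirnaMap:
    """Two-column TSV: precursor<TAB>mature, one pair per line."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path.name}:{lineno}: expected 2 fields, got {len(fields)}")
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ParseError(f"{path.name}: empty miRNA map")
    return MirnaMap.from_pairs(pairs)


def convert_mirna_ids(ids: Sequence[str], mirna_map: MirnaMap) -> tuple[list[str], list[str]]:
    """Expand a mixed precursor/mature list so every known counterpart form
    is present: precursors gain their mature forms and matures their
    precursors. Original order is preserved; additions are appended in
    lexicographic order. Returns ``(expanded_ids, unmapped_ids)`` where
    unmapped IDs are unknown to both map sides (kept, flagged).

    The expansion is idempotent.
    """
    seen: dict[str, None] = {}
    for i in ids:
        seen.setdefault(i)
    present = set(seen)
    additions: set[str] = set()
    unmapped: list[str] = []
    for i in seen:
        forward = mirna_map.precursor_to_mature.get(i)
        backward = mirna_map.mature_to_precursor.get(i)
        if forward is None and backward is None:
            unmapped.append(i)
            continue
        for counterpart in (forward or frozenset()) | (backward or frozenset()):
            if counterpart not in present:
                additions.add(counterpart)
    return list(seen) + sorted(additions), unmapped


def project_to_targets(input_list: InputList, interactome: Interactome) -> TargetProjection:
    """Map input regulators to the union of their target genes.

    The contributing map records, per target gene, which input regulators
    hit it — this is what lets result tables trace a supporting gene back
    to the miRNAs/TFs/CpGs that brought it in.
    """
    if input_list.input_kind != interactome.kind:
        raise ValueError(
            f"input kind {input_list.input_kind!r} does not match interactome kind {interactome.kind!r}"
        )
    adj = interactome.adjacency()
    contributing: dict[str, set[str]] = {}
    no_targets: list[str] = []
    for reg in sorted(input_list.mapped):
        targets = adj.get(reg, frozenset())
        if not targets:
            no_targets.append(reg)
            continue
        for g in targets:
            contributing.setdefault(g, set()).add(reg)
    if not contributing:
        raise ValueError("empty target set: no mapped regulator has any target")
    return TargetProjection(
        target_genes=frozenset(contributing),
        contributing={g: frozenset(rs) for g, rs in contributing.items()},
        regulators_without_targets=tuple(no_targets),
    )


def transform_db_to_mirnas(db: AnnotationDatabase, interactome: Interactome) -> AnnotationDatabase:
    """Rewrite a gene-based database in miRNA space: each term becomes the
    set of miRNAs targeting at least one of its genes. A miRNA appears once
    per term regardless of how many of the term's genes it targets. Terms
    whose genes have no regulators are dropped.
    """
    if db.element_kind != "gene":
        raise ValueError("transformation requires a gene-based database")
    if interactome.kind != "mirna":
        raise ValueError("transformation requires a miRNA interactome")
    gene_to_regs: dict[str, set[str]] = {}
    for r, g in interactome.edges:
        gene_to_regs.setdefault(g, set()).add(r)
    new_terms: dict[str, tuple[str, frozenset[str]]] = {}
    for tid, (name, genes) in db.terms.items():
        mirnas: set[str] = set()
        for g in genes:
            mirnas |= gene_to_regs.get(g, set())
        if mirnas:
            new_terms[tid] = (name, frozenset(mirnas))
    if not new_terms:
        raise ValueError("all terms empty after transformation to miRNA space")
    return AnnotationDatabase(source_name=db.source_name + ":mirna", terms=new_terms, element_kind="mirna")


def qc_report(
    input_list: InputList,
    universe: Universe,
    projection: Optional[TargetProjection] = None,
) -> dict:
    """Mapping quality-control counts, mirroring the 'annotated genes'
    report a user consults before trusting downstream statistics."""
    distinct = len(input_list.raw_ids) - input_list.n_duplicates
    in_universe = input_list.mapped & universe.elements
    report = {
        "raw": len(input_list.raw_ids),
        "duplicates": input_list.n_duplicates,
        "distinct": distinct,
        "mapped": len(input_list.mapped),
        "unmapped": len(input_list.unmapped),
        "unmapped_ids": list(input_list.unmapped),
        "in_universe": len(in_universe),
    }
    if projection is not None:
        report["target_genes"] = sorted(projection.target_genes)
        report["n_target_genes"] = len(projection.target_genes)
        report["regulators_without_targets"] = list(projection.regulators_without_targets)
    return report
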