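"""End-to-end analysis strategies and result export.

Four strategies cover the ways a regulatory-element list can be tested:

* ``targets-wallenius`` — project regulators to their target genes, fit the
  probability weighting function on the per-gene regulator count (or gene
  length / CpG count), and run the Wallenius test in gene space;
* ``targets-hypergeom`` — same projection, plain hypergeometric test (the
  naive, bias-blind baseline);
* ``transformed-db`` — rewrite each gene database in miRNA space (a term
  becomes the miRNAs targeting at least one of its genes) and test the
  miRNA list directly with the hypergeometric test;
* ``direct-annotations`` — test against databases whose elements already
  are miRNAs (TAM/HMDD/MNDR-style), hypergeometric; gene input lists are
  likewise tested directly against gene databases (Wallenius available via
  a gene-length table).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import bias, coannotation as coann_mod, id_mapping, stats
from .data_model import (
    AnnotationDatabase,
    GeneCovariateTable,
    InputList,
    Interactome,
    Universe,
    read_covariate_table,
    read_gmt,
    read_id_list,
    read_interactome,
    resolve_universe,
    write_results,
)

__all__ = ["RunConfig", "run", "export_graph"]

STRATEGIES = ("targets-wallenius", "targets-hypergeom", "transformed-db", "direct-annotations")
_KIND_TO_INTERACTOME = {"mirna": "mirna", "tf": "tf", "cpg": "cpg"}


@dataclass(frozen=True)
class RunConfig:
    input_path: str
    input_kind: str  # gene | mirna | tf | cpg
    strategy: str
    db_paths: tuple[str, ...]
    interactome_path: Optional[str] = None
    cpg_map_path: Optional[str] = None
    gene_lengths_path: Optional[str] = None
    mirna_map_path: Optional[str] = None
    universe_scope: str = "annotated"
    universe_file: Optional[str] = None  # custom set or whole-catalogue file
    odds_mode: str = "ratio-of-means"
    coannotation: str = "off"  # off | fpgrowth | fpmax
    min_support_frac: float = coann_mod.DEFAULT_MIN_SUPPORT_FRAC
    composite_background: str = "intersection"
    alpha: float = 0.05
    out_dir: str = "regset_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.input_kind not in ("gene", "mirna", "tf", "cpg"):
            raise ValueError(f"unknown input kind {self.input_kind!r}")
        if not self.db_paths:
            raise ValueError("at least one annotation database (--gmt) is required")
        if self.coannotation not in ("off", "fpgrowth", "fpmax"):
            raise ValueError(f"unknown coannotation mode {self.coannotation!r}")
        self.validate_resources()

    def validate_resources(self) -> None:
        needs_map = self.strategy in ("targets-wallenius", "targets-hypergeom", "transformed-db")
        if needs_map:
            if self.input_kind == "gene":
                raise ValueError(f"strategy {self.strategy!r} applies to regulator input, not genes")
            if self.input_kind == "cpg" and self.cpg_map_path is None:
                raise ValueError("CpG input requires --cpg-map")
            if self.input_kind in ("mirna", "tf") and self.interactome_path is None:
                raise ValueError(f"strategy {self.strategy!r} requires --interactome")
        if self.strategy == "transformed-db" and self.input_kind != "mirna":
            raise ValueError("the database transformation is only available for miRNA input")
        if self.strategy == "direct-annotations" and self.input_kind in ("tf", "cpg"):
            raise ValueError("direct annotation databases exist for miRNAs (and genes) only")
        if self.universe_scope in ("whole", "custom") and self.universe_file is None:
            raise ValueError(f"universe scope {self.universe_scope!r} requires --universe-file")


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def _resolve(
    cfg: RunConfig, dbs: Sequence[AnnotationDatabase], whole_catalogue: Optional[Sequence[str]]
) -> Universe:
    custom = read_id_list(cfg.universe_file) if cfg.universe_scope == "custom" else None
    return resolve_universe(cfg.universe_scope, dbs=dbs, catalogue=whole_catalogue, custom=custom)


def _load_regulator_map(cfg: RunConfig) -> Interactome:
    if cfg.input_kind == "cpg":
        return read_interactome(cfg.cpg_map_path, kind="cpg")
    return read_interactome(cfg.interactome_path, kind=_KIND_TO_INTERACTOME[cfg.input_kind])


def run(cfg: RunConfig) -> dict:
    """Execute one analysis; writes per-database result TSVs, a QC report,
    graph JSON exports and a structured log under cfg.out_dir. Returns a
    summary dict with the in-memory rows per database."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    _log(log, f"strategy={cfg.strategy} input_kind={cfg.input_kind} universe={cfg.universe_scope} seed={cfg.seed}")

    raw_ids = read_id_list(cfg.input_path)
    _log(log, f"input: {len(raw_ids)} raw identifiers from {cfg.input_path}")

    if cfg.input_kind == "mirna" and cfg.mirna_map_path is not None:
        mm = id_mapping.read_mirna_map(cfg.mirna_map_path)
        raw_ids, unknown = id_mapping.convert_mirna_ids(raw_ids, mm)
        _log(log, f"mirna-converter: expanded to {len(raw_ids)} ids ({len(unknown)} unknown to the map)")

    results: dict[str, list[stats.EnrichmentRow]] = {}
    summary: dict = {"config": cfg, "results": results}

    if cfg.strategy in ("targets-wallenius", "targets-hypergeom"):
        gene_dbs = [read_gmt(p, element_kind="gene") for p in cfg.db_paths]
        imap = _load_regulator_map(cfg)
        input_list = InputList.from_ids(raw_ids, cfg.input_kind, known=imap.regulators())
        projection = id_mapping.project_to_targets(input_list, imap)
        _log(log, f"projection: {len(input_list.mapped)} mapped regulators -> "
                  f"{len(projection.target_genes)} target genes "
                  f"({len(input_list.unmapped)} unmapped ids)")
        method = "wallenius" if cfg.strategy == "targets-wallenius" else "hypergeom"
        whole = sorted(imap.targets())
        qc_universe = None
        for db in gene_dbs:
            universe = _resolve(cfg, [db], whole)
            qc_universe = qc_universe or universe
            pwf = None
            if method == "wallenius":
                cov = _gene_space_covariate(cfg, imap, universe)
                membership = {g: int(g in projection.target_genes) for g in universe.elements}
                pwf = bias.fit_pwf(membership, cov)
                _log(log, f"{db.source_name}: PWF fitted ({pwf.fit_meta['method']}) on {len(membership)} genes")
            rows = stats.run_sea(
                projection.target_genes, db, universe,
                method=method, pwf=pwf, odds_mode=cfg.odds_mode,
                input_provenance=projection.contributing,
            )
            results[db.source_name] = rows
            _log(log, f"{db.source_name}: tested {len(rows)} terms "
                      f"({sum(r.padj <= cfg.alpha for r in rows)} with padj <= {cfg.alpha})")
        summary["qc"] = id_mapping.qc_report(input_list, qc_universe, projection)
        test_space_input = frozenset(projection.target_genes)
        coann_dbs: Sequence[AnnotationDatabase] = gene_dbs
        coann_universe = _resolve(cfg, gene_dbs, whole)
        coann_pwf = None
        if method == "wallenius":
            cov = _gene_space_covariate(cfg, imap, coann_universe)
            membership = {g: int(g in projection.target_genes) for g in coann_universe.elements}
            coann_pwf = bias.fit_pwf(membership, cov)

    elif cfg.strategy == "transformed-db":
        imap = _load_regulator_map(cfg)
        gene_dbs = [read_gmt(p, element_kind="gene") for p in cfg.db_paths]
        mirna_dbs = [id_mapping.transform_db_to_mirnas(db, imap) for db in gene_dbs]
        for gdb, mdb in zip(gene_dbs, mirna_dbs):
            _log(log, f"{gdb.source_name}: transformed {len(gdb)} gene terms -> {len(mdb)} miRNA terms")
        input_list = InputList.from_ids(raw_ids, cfg.input_kind, known=imap.regulators())
        whole = sorted(imap.regulators())
        qc_universe = None
        for mdb in mirna_dbs:
            universe = _resolve(cfg, [mdb], whole)
            qc_universe = qc_universe or universe
            rows = stats.run_sea(input_list.mapped, mdb, universe, method="hypergeom")
            results[mdb.source_name] = rows
            _log(log, f"{mdb.source_name}: tested {len(rows)} terms "
                      f"({sum(r.padj <= cfg.alpha for r in rows)} with padj <= {cfg.alpha})")
        summary["qc"] = id_mapping.qc_report(input_list, qc_universe)
        test_space_input = frozenset(input_list.mapped)
        coann_dbs = mirna_dbs
        coann_universe = _resolve(cfg, mirna_dbs, whole)
        coann_pwf = None

    else:  # direct-annotations
        kind = "mirna" if cfg.input_kind == "mirna" else "gene"
        dbs = [read_gmt(p, element_kind=kind) for p in cfg.db_paths]
        known: set[str] = set()
        for db in dbs:
            known |= db.annotated_universe()
        input_list = InputList.from_ids(raw_ids, cfg.input_kind, known=known)
        whole = read_id_list(cfg.universe_file) if cfg.universe_scope == "whole" else None
        qc_universe = None
        for db in dbs:
            universe = _resolve(cfg, [db], whole)
            qc_universe = qc_universe or universe
            pwf = None
            method = "hypergeom"
            if cfg.input_kind == "gene" and cfg.gene_lengths_path is not None:
                method = "wallenius"
                cov = bias.bias_covariate(universe.elements, read_covariate_table(cfg.gene_lengths_path, "gene_length"))
                membership = {g: int(g in input_list.mapped) for g in universe.elements}
                pwf = bias.fit_pwf(membership, cov)
                _log(log, f"{db.source_name}: PWF fitted on gene length ({pwf.fit_meta['method']})")
            rows = stats.run_sea(input_list.mapped, db, universe, method=method, pwf=pwf, odds_mode=cfg.odds_mode)
            results[db.source_name] = rows
            _log(log, f"{db.source_name}: tested {len(rows)} terms "
                      f"({sum(r.padj <= cfg.alpha for r in rows)} with padj <= {cfg.alpha})")
        summary["qc"] = id_mapping.qc_report(input_list, qc_universe)
        test_space_input = frozenset(input_list.mapped)
        coann_dbs = dbs
        coann_universe = _resolve(cfg, dbs, whole)
        coann_pwf = None

    # ------------------------------------------------------------------ MEA
    if cfg.coannotation != "off":
        ts = coann_mod.build_transactions(sorted(test_space_input), coann_dbs)
        miner = coann_mod.mine_closed if cfg.coannotation == "fpgrowth" else coann_mod.mine_maximal
        mined = miner(ts, cfg.min_support_frac)
        _log(log, f"coannotation ({cfg.coannotation}): {len(mined)} itemsets at "
                  f"min support {cfg.min_support_frac:.0%} of {ts.n_elements} elements "
                  f"({ts.n_unannotated} unannotated elements dropped)")
        carows = coann_mod.test_coannotations(
            mined, test_space_input, coann_dbs, coann_universe,
            method="wallenius" if coann_pwf is not None else "hypergeom",
            pwf=coann_pwf, odds_mode=cfg.odds_mode,
            composite_background=cfg.composite_background,
        )
        summary["coannotations"] = carows
        write_results(carows, out_dir / "coannotations.tsv", extra_columns=["coannotation"])

    # ------------------------------------------------------------- artifacts
    for source, rows in results.items():
        write_results(rows, out_dir / f"results_{source}.tsv")
        export_graph(rows, out_dir / f"graph_{source}.json")
    with open(out_dir / "qc_report.json", "w") as fh:
        json.dump(summary["qc"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    summary["log"] = log
    return summary


def _gene_space_covariate(cfg: RunConfig, imap: Interactome, universe: Universe) -> GeneCovariateTable:
    """Bias covariate for gene-space Wallenius runs: regulator (or probe)
    count from the full map; a gene-length table overrides for gene input."""
    if cfg.input_kind == "gene":
        if cfg.gene_lengths_path is None:
            raise ValueError("gene input with Wallenius requires --gene-lengths")
        return bias.bias_covariate(universe.elements, read_covariate_table(cfg.gene_lengths_path, "gene_length"))
    return bias.bias_covariate(universe.elements, imap)


def export_graph(rows: Sequence[stats.EnrichmentRow], path: str | Path) -> None:
    """Static term–element membership network: term nodes weighted by
    −log10(padj), element nodes, membership edges. Stable ordering."""
    rows = list(rows)
    if not rows:
        raise ValueError("refusing to export an empty result set")
    nodes: list[dict] = []
    edges: list[dict] = []
    seen_elements: dict[str, None] = {}
    for r in rows:
        nodes.append({
            "id": r.term_id,
            "type": "term",
            "label": r.term_name,
            "weight": round(-math.log10(max(r.padj, stats.PVALUE_FLOOR)), 6),
        })
        for e in sorted(r.support):
            seen_elements.setdefault(e)
            edges.append({"source": r.term_id, "target": e})
    nodes.extend({"id": e, "type": "element"} for e in seen_elements)
    with open(path, "w") as fh:
        json.dump({"nodes": nodes, "edges": edges}, fh, indent=1, sort_keys=True)
        fh.write("\n")
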