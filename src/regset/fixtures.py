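"""Seeded generators for every input the tool consumes.

Real regulator→target interactomes are heavy-tailed: a minority of genes is
targeted by many miRNAs/TFs (or carries many methylation probes) and those
genes dominate any target-gene projection. Annotation terms concentrated on
such genes then look enriched even for random inputs — exactly the
selection bias the Wallenius test corrects. The generators here reproduce
that structure with a controllable coupling, so the whole statistical
behaviour of the package is testable without any database download.

All randomness flows from the explicit seed in the config; the same seed
gives byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .data_model import AnnotationDatabase, InputList, Interactome, write_gmt
from .id_mapping import MirnaMap

__all__ = [
    "FixtureConfig",
    "generate_interactome",
    "generate_annotations",
    "generate_null_input",
    "generate_mirna_map",
    "write_interactome_tsv",
    "write_mirna_map_tsv",
]


@dataclass(frozen=True)
class FixtureConfig:
    n_genes: int = 1000
    n_regulators: int = 200
    degree_distribution: str = "power_law"  # or "uniform"
    power_law_alpha: float = 2.0
    power_law_scale: float = 5.0  # multiplies the Pareto draw for out-degrees
    uniform_out_degree: int = 5
    n_terms: int = 50
    term_size_range: tuple[int, int] = (15, 40)
    bias_coupling: float = 1.0  # 0 = terms uniform; 1 = term genes sampled ∝ regulator count
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_regulators, self.n_terms) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.bias_coupling <= 1.0):
            raise ValueError("bias_coupling must lie in [0, 1]")
        lo, hi = self.term_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid term_size_range")
        if self.degree_distribution not in ("uniform", "power_law"):
            raise ValueError(f"unknown degree distribution {self.degree_distribution!r}")


def _gene_names(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n + 1)]


def _regulator_names(n: int) -> list[str]:
    return [f"reg{i:04d}" for i in range(1, n + 1)]


def _out_degrees(cfg: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.degree_distribution == "uniform":
        d = np.full(cfg.n_regulators, cfg.uniform_out_degree)
    else:
        # discretised, scaled Pareto truncated to [1, n_genes]: heavy-tailed, bounded
        raw = cfg.power_law_scale * (1.0 - rng.random(cfg.n_regulators)) ** (-1.0 / cfg.power_law_alpha)
        d = np.clip(np.floor(raw).astype(int), 1, cfg.n_genes)
    if int(d.max()) > cfg.n_genes:
        raise ValueError("infeasible config: out-degree exceeds number of genes")
    return d


def generate_interactome(cfg: FixtureConfig, path: Optional[str | Path] = None) -> Interactome:
    """Draw one regulator→target-gene interactome.

    Each regulator's out-degree follows the configured distribution. Under
    ``uniform`` the targets are sampled uniformly; under ``power_law`` the
    genes additionally carry Pareto popularity weights and regulators
    attach preferentially to popular genes. Both mechanisms act in real
    interactomes (hub regulators and hub genes), and the preferential
    attachment is what makes the per-gene regulator count heavy-tailed —
    the bias source the annotation generator can couple to.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    regs = _regulator_names(cfg.n_regulators)
    degrees = _out_degrees(cfg, rng)
    if cfg.degree_distribution == "power_law":
        popularity = (1.0 - rng.random(cfg.n_genes)) ** (-1.0 / cfg.power_law_alpha)
        p = popularity / popularity.sum()
    else:
        p = None
    edges: set[tuple[str, str]] = set()
    for reg, d in zip(regs, degrees):
        targets = rng.choice(cfg.n_genes, size=int(d), replace=False, p=p)
        for t in targets:
            edges.add((reg, genes[t]))
    interactome = Interactome(kind="mirna", edges=frozenset(edges))
    if path is not None:
        write_interactome_tsv(interactome, path)
    return interactome


def generate_annotations(
    cfg: FixtureConfig,
    interactome: Interactome,
    path: Optional[str | Path] = None,
) -> AnnotationDatabase:
    """Draw an annotation database over the interactome's gene space.

    With coupling β each term's genes are sampled with probability
    ∝ (1−β)·1 + β·regulator_count(g): β=0 gives unbiased terms, β=1 terms
    made of heavily targeted genes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = _gene_names(cfg.n_genes)
    counts = interactome.regulator_count()
    weights = np.array(
        [(1.0 - cfg.bias_coupling) + cfg.bias_coupling * counts.get(g, 0) for g in genes]
    )
    if weights.sum() <= 0:
        raise ValueError("degenerate config: all sampling weights are zero")
    p = weights / weights.sum()
    lo, hi = cfg.term_size_range
    if hi > cfg.n_genes:
        raise ValueError("term size exceeds the gene universe")
    n_choosable = int(np.sum(p > 0))
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(1, cfg.n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, n_choosable)
        idx = rng.choice(cfg.n_genes, size=size, replace=False, p=p)
        terms[f"T{i:04d}"] = (f"synthetic term {i}", frozenset(genes[j] for j in idx))
    db = AnnotationDatabase(source_name="synthetic", terms=terms, element_kind="gene")
    if path is not None:
        write_gmt(db, path)
    return db


def generate_null_input(
    interactome: Interactome,
    n_pick: int,
    seed: int,
) -> InputList:
    """Uniform random regulator sample without replacement — the randomised
    control input against which false-positive rates are measured."""
    regs = sorted(interactome.regulators())
    if n_pick > len(regs):
        raise ValueError(f"n_pick={n_pick} exceeds the {len(regs)} available regulators")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(regs), size=n_pick, replace=False)
    ids = [regs[i] for i in sorted(picked)]
    return InputList.from_ids(ids, input_kind=interactome.kind, known=regs)


def generate_mirna_map(n_precursors: int, seed: int, path: Optional[str | Path] = None) -> MirnaMap:
    """Toy precursor↔mature map: precursor syn-mir-<i> gets one or two
    mature forms (-5p/-3p)."""
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    for i in range(1, n_precursors + 1):
        pre = f"syn-mir-{i}"
        arms = ["-5p", "-3p"] if rng.random() < 0.5 else [rng.choice(["-5p", "-3p"])]
        for arm in arms:
            pairs.append((pre, pre.replace("mir", "miR") + arm))
    mm = MirnaMap.from_pairs(pairs)
    if path is not None:
        write_mirna_map_tsv(mm, path)
    return mm


def write_interactome_tsv(interactome: Interactome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#regulator\ttarget_gene\n")
        for r, g in sorted(interactome.edges):
            fh.write(f"{r}\t{g}\n")


def write_mirna_map_tsv(mm: MirnaMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#precursor\tmature\n")
        for p in sorted(mm.precursor_to_mature):
            for m in sorted(mm.precursor_to_mature[p]):
                fh.write(f"{p}\t{m}\n")
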