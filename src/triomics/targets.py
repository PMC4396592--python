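"""Overlap of negative significant associations with in-silico target lists.

Target-prediction pair lists (one per algorithm) are consumed as two-column
TSV files; a putative direct interaction is a negative, significant
association whose (miRNA, gene) pair is predicted by at least k of the
supplied algorithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .univariate import AssociationMatrix

__all__ = ["TargetPredictionDB", "load_targets", "putative_direct"]


def _norm(identifier: str) -> str:
    return str(identifier).strip().lower()


@dataclass
class TargetPredictionDB:
    """Per-algorithm sets of predicted (miRNA, gene) pairs, identifiers
    case-folded."""

    algorithms: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    @property
    def n_algorithms(self) -> int:
        return len(self.algorithms)

    def vote_count(self, mirna: str, gene: str) -> int:
        pair = (_norm(mirna), _norm(gene))
        return sum(pair in pairs for pairs in self.algorithms.values())


def load_targets(files: dict[str, str]) -> TargetPredictionDB:
    """Read one two-column (miRNA, gene) TSV per algorithm.

    A header line is optional and detected by the literal column names
    ``mirna``/``gene``. Duplicate pairs are stored once; malformed lines
    raise with their line number.
    """
    db = TargetPredictionDB()
    for algorithm, path in files.items():
        pairs: set[tuple[str, str]] = set()
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(fields)}"
                    )
                a, b = (_norm(f) for f in fields)
                if lineno == 1 and {a, b} & {"mirna", "gene", "mirna_id", "gene_id"}:
                    continue  # header
                if not a or not b:
                    raise ValueError(f"{path}:{lineno}: empty identifier")
                pairs.add((a, b))
        if not pairs:
            warnings.warn(
                f"target list {algorithm!r} ({path}) is empty",
                UserWarning,
                stacklevel=2,
            )
        db.algorithms[algorithm] = pairs
    return db


def putative_direct(
    assoc: AssociationMatrix,
    db: TargetPredictionDB,
    gene_map: dict[str, str],
    min_algorithms: int = 2,
) -> list[tuple[str, str]]:
    """(miRNA, gene) pairs that are significant, negative and predicted by
    at least ``min_algorithms`` algorithms; sorted for determinism."""
    if min_algorithms > db.n_algorithms:
        raise ValueError(
            f"min_algorithms = {min_algorithms} exceeds the "
            f"{db.n_algorithms} available algorithm(s)"
        )
    hits = []
    for i, protein_id in enumerate(assoc.protein_ids):
        gene = gene_map.get(protein_id, protein_id)
        for j, mirna_id in enumerate(assoc.mirna_ids):
            if not assoc.significant[i, j] or assoc.beta[i, j] >= 0:
                continue
            if db.vote_count(mirna_id, gene) >= min_algorithms:
                hits.append((mirna_id, gene))
    return sorted(set(hits))


def write_pairs(pairs: list[tuple[str, str]], path) -> None:
    pd.DataFrame(pairs, columns=["mirna", "gene"]).to_csv(path, sep="\t", index=False)
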