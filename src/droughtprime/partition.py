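"""Partition gene-level DEG calls by genotype exclusivity and by organ.

Per organ, the drought-DEG universe splits into three disjoint classes —
genes differentially expressed in the tolerant genotype only, in the
sensitive genotype only, or in both ("shared") — whose counts must sum to
the organ's total. Across organs the union of per-organ DEG universes
splits into root-exclusive, leaf-exclusive and both-organ classes. Genes
DE in both genotypes with opposite directions still count as shared but
carry a direction-discordance flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable


def _as_set(genes: Iterable[str]) -> set[str]:
    return set(genes)


@dataclass(frozen=True)
class GenotypePartition:
    tolerant_only: frozenset[str]
    sensitive_only: frozenset[str]
    shared: frozenset[str]

    @property
    def total(self) -> int:
        return len(self.tolerant_only) + len(self.sensitive_only) + len(self.shared)

    def counts(self) -> dict[str, int]:
        return {
            "tolerant_only": len(self.tolerant_only),
            "sensitive_only": len(self.sensitive_only),
            "shared": len(self.shared),
            "total": self.total,
        }


@dataclass(frozen=True)
class OrganPartition:
    root_exclusive: frozenset[str]
    leaf_exclusive: frozenset[str]
    both: frozenset[str]

    def counts(self) -> dict[str, int]:
        return {
            "root_exclusive": len(self.root_exclusive),
            "leaf_exclusive": len(self.leaf_exclusive),
            "both": len(self.both),
            "total": len(self.root_exclusive) + len(self.leaf_exclusive) + len(self.both),
        }


def partition_by_genotype(
    deg_tolerant: Iterable[str], deg_sensitive: Iterable[str]
) -> GenotypePartition:
    """Two-set partition of one organ's DEG universe by genotype.

    Classes are pairwise disjoint and their union is the universe, so
    |tolerant_only| + |sensitive_only| + |shared| = |union| always holds.
    """
    tol, sen = _as_set(deg_tolerant), _as_set(deg_sensitive)
    part = GenotypePartition(
        tolerant_only=frozenset(tol - sen),
        sensitive_only=frozenset(sen - tol),
        shared=frozenset(tol & sen),
    )
    assert part.total == len(tol | sen)
    return part


def partition_by_organ(
    root_universe: Iterable[str], leaf_universe: Iterable[str]
) -> OrganPartition:
    """Two-set partition of the pooled DEG universe by organ."""
    root, leaf = _as_set(root_universe), _as_set(leaf_universe)
    part = OrganPartition(
        root_exclusive=frozenset(root - leaf),
        leaf_exclusive=frozenset(leaf - root),
        both=frozenset(root & leaf),
    )
    assert part.counts()["total"] == len(root | leaf)
    return part


def discordant_shared(
    shared: Iterable[str],
    direction_tolerant: dict[str, str],
    direction_sensitive: dict[str, str],
) -> set[str]:
    """Shared genes whose call directions disagree between genotypes."""
    return {
        g
        for g in shared
        if direction_tolerant.get(g) is not None
        and direction_sensitive.get(g) is not None
        and direction_tolerant[g] != direction_sensitive[g]
    }
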