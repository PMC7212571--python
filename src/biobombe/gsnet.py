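"""Gene-set membership networks and degree-preserving XSwap permutation.

A gene-set collection (GMT) defines a bipartite network between gene sets
and genes; its biadjacency matrix H (gene sets x genes, binary) is the
object projected onto compression weight matrices. The permutation null
is built with the XSwap algorithm: repeatedly pick two edges and exchange
their endpoints when doing so creates no duplicate edge, which randomizes
connectivity while preserving every node's degree exactly. Degree
preservation is the point — it controls for hub genes and for gene-set
size when scoring projections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "MembershipMatrix",
    "PermutedEnsemble",
    "read_gmt",
    "build_membership",
    "xswap",
    "permuted_ensemble",
]


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for s, genes in self.sets.items():
            bad = [g for g in genes if g not in uni]
            if bad:
                raise ValueError(f"set {s!r} has members outside the universe: {bad[:3]}")

    @property
    def n_sets(self) -> int:
        return len(self.sets)


@dataclass
class MembershipMatrix:
    """Binary gene-sets x genes biadjacency matrix H."""

    H: pd.DataFrame  # index = set names, columns = gene IDs, values in {0,1}

    def __post_init__(self) -> None:
        vals = self.H.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("membership matrix must be binary")

    @property
    def edge_count(self) -> int:
        return int(self.H.to_numpy().sum())

    @property
    def set_sizes(self) -> pd.Series:
        return self.H.sum(axis=1)

    @property
    def gene_degrees(self) -> pd.Series:
        return self.H.sum(axis=0)

    def edges(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.H.to_numpy())
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass
class PermutedEnsemble:
    original: MembershipMatrix
    permutations: list[MembershipMatrix]
    base_seed: int
    multiplier: int

    def __len__(self) -> int:
        return len(self.permutations)

    def manifest(self) -> dict:
        return {
            "n_permutations": len(self.permutations),
            "base_seed": self.base_seed,
            "multiplier": self.multiplier,
        }


# ---------------------------------------------------------------------------
# GMT parsing
# ---------------------------------------------------------------------------

def read_gmt(path, universe) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...).

    Members outside ``universe`` are dropped; duplicate members within a
    set are collapsed (first occurrence kept); a set left empty after
    filtering is dropped with a warning.
    """
    uni = set(map(str, universe))
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} is malformed (needs name, "
                    f"description and at least one member)"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            seen: list[str] = []
            for g in fields[2:]:
                if g in uni and g not in seen:
                    seen.append(g)
            if not seen:
                warnings.warn(
                    f"set {name!r} empty after universe filtering; dropped",
                    stacklevel=2,
                )
                continue
            sets[name] = seen
    return GeneSetCollection(name=str(path), sets=sets, universe=list(map(str, universe)))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# membership matrix
# ---------------------------------------------------------------------------

def build_membership(collection: GeneSetCollection, gene_order) -> MembershipMatrix:
    """Binary H with rows = set names, columns = exactly ``gene_order``."""
    gene_order = [str(g) for g in gene_order]
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    missing = set(gene_order) - set(collection.universe)
    if missing:
        raise ValueError(f"gene_order contains genes outside the universe: {sorted(missing)[:3]}")
    col_index = {g: i for i, g in enumerate(gene_order)}
    h = np.zeros((len(collection.sets), len(gene_order)), dtype=np.int8)
    names = list(collection.sets)
    for i, name in enumerate(names):
        for g in collection.sets[name]:
            j = col_index.get(g)
            if j is not None:
                h[i, j] = 1
    return MembershipMatrix(pd.DataFrame(h, index=names, columns=gene_order))


# ---------------------------------------------------------------------------
# XSwap
# ---------------------------------------------------------------------------

def xswap(H: MembershipMatrix, multiplier: int = 10, seed: int = 0) -> MembershipMatrix:
    """Degree-preserving randomization of the bipartite membership network.

    Runs ``multiplier * edge_count`` swap attempts. Each attempt draws two
    distinct edges (s1, g1), (s2, g2) uniformly with replacement; if the
    four endpoints are pairwise usable (s1 != s2, g1 != g2) and neither
    (s1, g2) nor (s2, g1) already exists, the two edges are rewired to
    (s1, g2), (s2, g1). Failed attempts count toward the budget. Row and
    column sums are preserved exactly; deterministic given ``seed``.
    """
    edges = H.edges()
    m = len(edges)
    if m < 2:
        return MembershipMatrix(H.H.copy())
    edge_set = set(edges)
    rng = np.random.default_rng(seed)
    n_attempts = multiplier * m
    pick = rng.integers(0, m, size=(n_attempts, 2))
    for a, b in pick:
        if a == b:
            continue
        s1, g1 = edges[a]
        s2, g2 = edges[b]
        if s1 == s2 or g1 == g2:
            continue
        if (s1, g2) in edge_set or (s2, g1) in edge_set:
            continue
        edge_set.discard((s1, g1))
        edge_set.discard((s2, g2))
        edge_set.add((s1, g2))
        edge_set.add((s2, g1))
        edges[a] = (s1, g2)
        edges[b] = (s2, g1)
    h = np.zeros(H.H.shape, dtype=np.int8)
    rows, cols = zip(*edges)
    h[list(rows), list(cols)] = 1
    return MembershipMatrix(pd.DataFrame(h, index=H.H.index, columns=H.H.columns))


def permuted_ensemble(
    H: MembershipMatrix,
    n_permutations: int = 10,
    base_seed: int = 0,
    multiplier: int = 10,
) -> PermutedEnsemble:
    """Independent XSwap runs with seeds derived from ``base_seed``."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    children = np.random.SeedSequence(base_seed).generate_state(n_permutations)
    perms = [
        xswap(H, multiplier=multiplier, seed=int(s) % (2 ** 31))
        for s in children
    ]
    return PermutedEnsemble(H, perms, base_seed, multiplier)


# ---------------------------------------------------------------------------
# serialization (sparse triplet TSV + JSON manifest)
# ---------------------------------------------------------------------------

def write_membership_tsv(H: MembershipMatrix, path) -> None:
    rows, cols = np.nonzero(H.H.to_numpy())
    with open(path, "w") as fh:
        fh.write("set\tgene\tvalue\n")
        for r, c in zip(rows, cols):
            fh.write(f"{H.H.index[r]}\t{H.H.columns[c]}\t1\n")


def read_membership_tsv(path, set_order, gene_order) -> MembershipMatrix:
    triplets = pd.read_csv(path, sep="\t", dtype={"set": str, "gene": str})
    h = pd.DataFrame(
        np.zeros((len(set_order), len(gene_order)), dtype=np.int8),
        index=list(set_order), columns=[str(g) for g in gene_order],
    )
    for _, row in triplets.iterrows():
        h.loc[row["set"], row["gene"]] = 1
    return MembershipMatrix(h)


def write_ensemble(ensemble: PermutedEnsemble, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_membership_tsv(ensemble.original, directory / "membership.tsv")
    for i, perm in enumerate(ensemble.permutations):
        write_membership_tsv(perm, directory / f"permutation_{i}.tsv")
    manifest = ensemble.manifest()
    manifest["set_order"] = list(ensemble.original.H.index)
    manifest["gene_order"] = list(ensemble.original.H.columns)
    (directory / "manifest.json").write_text(json.dumps(manifest))


def read_ensemble(directory) -> PermutedEnsemble:
    from pathlib import Path

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    set_order, gene_order = manifest["set_order"], manifest["gene_order"]
    original = read_membership_tsv(directory / "membership.tsv", set_order, gene_order)
    perms = [
        read_membership_tsv(directory / f"permutation_{i}.tsv", set_order, gene_order)
        for i in range(manifest["n_permutations"])
    ]
    return PermutedEnsemble(original, perms, manifest["base_seed"], manifest["multiplier"])
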