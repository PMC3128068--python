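"""Panel genotypes, allele frequencies, Rogers distance, UPGMA.

The panel is a markers x clones matrix of dosage-blind calls AA/AB/BB:
tetraploid heterozygous classes (AAAB, AABB, ABBB) are all scored AB
because allele dosage cannot be distinguished on the genotyping
platform.  Frequency estimation therefore treats every clone as
contributing two alleles (AB = one A + one B); in true tetraploids this
biases estimates toward 0.5, a documented limitation of the encoding,
not of the estimator.

Rogers distance between two populations over L loci:

    D = (1/L) * sum_l sqrt( (1/2) * sum_a (p_la - q_la)^2 )

which for a biallelic locus reduces to |p_l - q_l|.  Markers missing in
either group of a pair are excluded pairwise from that pair's L.

UPGMA joins the closest pair of clusters at height d/2 and updates
distances by size-weighted arithmetic means, yielding an ultrametric
tree; ties break on the lexicographically smallest cluster-index pair
for determinism.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "NA"
CALLS = ("AA", "AB", "BB")


class NoDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotype containers


def collapse_tetraploid(raw: str, ploidy: int = 4) -> str:
    """Collapse an allele string over {A,B} to a dosage-blind call.

    AAAA -> AA, BBBB -> BB, any mixed class (AAAB, AABB, ABBB) -> AB;
    diploid strings pass through (AA/AB/BB).  The missing token maps to
    itself.
    """
    if raw in (MISSING, "", None):
        return MISSING
    if len(raw) != ploidy or any(ch not in "AB" for ch in raw):
        raise ValueError(f"bad genotype string {raw!r} for ploidy {ploidy}")
    n_a = raw.count("A")
    if n_a == ploidy:
        return "AA"
    if n_a == 0:
        return "BB"
    return "AB"


@dataclass
class GenotypeMatrix:
    """markers x clones calls in {AA, AB, BB, NA}."""

    data: pd.DataFrame

    def __post_init__(self):
        bad = set(np.unique(self.data.to_numpy().astype(str))) - set(CALLS) - {MISSING}
        if bad:
            raise ValueError(f"unknown genotype calls: {sorted(bad)}")

    @property
    def markers(self) -> list[str]:
        return list(self.data.index)

    @property
    def clones(self) -> list[str]:
        return list(self.data.columns)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="marker")

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="marker", dtype=str).fillna(MISSING))


@dataclass
class GroupMap:
    """clone -> group label; ungrouped clones are excluded from analysis."""

    assignments: dict[str, str]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for clone, g in self.assignments.items():
            out.setdefault(g, []).append(clone)
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("clone\tgroup\n")
            for clone, g in self.assignments.items():
                fh.write(f"{clone}\t{g}\n")

    @classmethod
    def read_tsv(cls, path) -> "GroupMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["clone"], df["group"])))


@dataclass
class GroupFrequencies:
    """Per (marker, group): allele-A frequency and sample size used."""

    p: pd.DataFrame  # markers x groups, NaN where no data
    n: pd.DataFrame  # non-missing clone counts


def group_allele_frequencies(
    matrix: GenotypeMatrix, group_map: GroupMap
) -> GroupFrequencies:
    """p = (2 n_AA + n_AB) / (2 n_nonmissing) per marker per group.

    Missing calls are excluded; a (marker, group) pair with no data is
    NaN.  A group with no data at every marker raises NoDataError.
    """
    groups = group_map.groups()
    p = pd.DataFrame(index=matrix.data.index, columns=list(groups), dtype=float)
    n = pd.DataFrame(0, index=matrix.data.index, columns=list(groups), dtype=int)
    for g, clones in groups.items():
        present = [c for c in clones if c in matrix.data.columns]
        sub = matrix.data[present]
        n_aa = (sub == "AA").sum(axis=1)
        n_ab = (sub == "AB").sum(axis=1)
        n_bb = (sub == "BB").sum(axis=1)
        n_tot = n_aa + n_ab + n_bb
        if (n_tot == 0).all():
            raise NoDataError(f"group {g!r} has no non-missing calls at any marker")
        with np.errstate(invalid="ignore"):
            p[g] = (2 * n_aa + n_ab) / (2 * n_tot).replace(0, np.nan)
        n[g] = n_tot
    return GroupFrequencies(p=p, n=n)


# ---------------------------------------------------------------------------
# Rogers distance


def rogers_locus(p_alleles, q_alleles) -> float:
    """Single-locus Rogers distance from allele->frequency mappings."""
    alleles = set(p_alleles) | set(q_alleles)
    ss = sum((p_alleles.get(a, 0.0) - q_alleles.get(a, 0.0)) ** 2 for a in alleles)
    return math.sqrt(0.5 * ss)


def rogers_distance(p_loci, q_loci) -> float:
    """Mean single-locus Rogers distance over loci present in both inputs.

    Inputs are sequences of allele->frequency mappings (one per locus);
    a locus where either side is None/empty is excluded from L.
    """
    terms = [
        rogers_locus(pa, qa)
        for pa, qa in zip(p_loci, q_loci)
        if pa and qa
    ]
    if not terms:
        raise NoDataError("no loci with frequencies in both groups")
    return float(np.mean(terms))


def _biallelic_loci(p: pd.Series):
    """markers series of allele-A frequencies -> per-locus allele maps."""
    return [
        None if pd.isna(v) else {"A": float(v), "B": 1.0 - float(v)}
        for v in p.to_numpy()
    ]


def rogers_distance_biallelic(p: pd.Series, q: pd.Series) -> float:
    return rogers_distance(_biallelic_loci(p), _biallelic_loci(q))


def distance_matrix(freqs: GroupFrequencies) -> pd.DataFrame:
    """Symmetric Rogers distance matrix over groups (pairwise-complete
    markers per pair; zero diagonal)."""
    groups = list(freqs.p.columns)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            d = rogers_distance_biallelic(freqs.p[g1], freqs.p[g2])
            mat.loc[g1, g2] = mat.loc[g2, g1] = d
    return mat


def write_distance_tsv(path, mat: pd.DataFrame, seed=None, config=None) -> None:
    from .io import provenance_lines

    with open(path, "w") as fh:
        for line in provenance_lines(seed=seed, config=config, comment_char="#"):
            fh.write(line + "\n")
        fh.write("#missing_markers=pairwise-excluded\n")
        mat.to_csv(fh, sep="\t", float_format="%.6f", index_label="group")


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class UpgmaNode:
    """A node of the ultrametric UPGMA tree (leaf when children empty)."""

    label: str | None
    height: float
    children: list["UpgmaNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_depths(self) -> list[float]:
        """Root-to-leaf path lengths (for ultrametricity checks)."""
        if self.is_leaf:
            return [0.0]
        out = []
        for ch in self.children:
            out.extend(self.height - ch.height + d for d in ch.leaf_depths())
        return out


def upgma(mat: pd.DataFrame) -> UpgmaNode:
    """Agglomerate a symmetric zero-diagonal distance matrix.

    Cluster distances update by size-weighted arithmetic means; the
    closest pair joins at height d/2.  Ties break on the smallest
    (i, j) active-cluster index pair.
    """
    labels = list(mat.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    arr = mat.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(arr) != 0) or np.any(arr < 0):
        raise ValueError("distance matrix must be non-negative with zero diagonal")

    nodes = {i: UpgmaNode(lab, 0.0) for i, lab in enumerate(labels)}
    sizes = {i: 1 for i in nodes}
    dist = {
        (i, j): float(arr[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(nodes) > 1:
        (i, j), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = UpgmaNode(None, d / 2.0, [nodes[i], nodes[j]])
        ni, nj = sizes[i], sizes[j]
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(k, next_id), max(k, next_id))] = (ni * dik + nj * djk) / (
                ni + nj
            )
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        del nodes[i], nodes[j], sizes[i], sizes[j]
        nodes[next_id] = new
        sizes[next_id] = ni + nj
        next_id += 1
    return next(iter(nodes.values()))


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _quote_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: UpgmaNode, path=None) -> str:
    """Serialize with 6-decimal branch lengths; returns the Newick text."""

    def render(node: UpgmaNode, parent_height: float | None) -> str:
        if node.is_leaf:
            s = _quote_label(node.label)
        else:
            s = "(" + ",".join(render(ch, node.height) for ch in node.children) + ")"
        if parent_height is not None:
            s += f":{parent_height - node.height:.6f}"
        return s

    text = render(tree, None) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
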