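"""Distance-based phylogenetics for protein alignments.

Implements pairwise maximum-likelihood distances under the Jones-Taylor-
Thornton (JTT) empirical amino-acid substitution model, Saitou-Nei
neighbour joining with the Studier-Keppler criterion, and nonparametric
bootstrap clade supports by column resampling.

The JTT model is a general time-reversible Markov process on the 20 amino
acids: the instantaneous rate matrix is Q_ij = s_ij * pi_j (i != j) with
symmetric exchangeabilities s and equilibrium frequencies pi, normalised so
that one unit of time corresponds to one expected substitution per site.
The exchangeabilities and frequencies are the published Jones et al. (1992)
values, shipped as a data file whose checksum is asserted at load.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar

from .records import AMINO_ACIDS, GAP

__all__ = [
    "JTTModel",
    "Msa",
    "DistanceMatrix",
    "PhyloTree",
    "trim_msa",
    "jtt_distance",
    "jtt_distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "is_monophyletic",
    "parse_newick",
]

_JTT_FILE = "jtt_jones1992.dat"
_JTT_SHA256 = "d7b8bf13019674f05ff41ea1059a6fa033c160cbeeb55ad9e386edd402a9bc4e"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CODE = 20  # integer code for a gap column


class JTTModel:
    """The JTT substitution model with spectral transition matrices.

    Because the model is reversible, ``diag(pi)^(1/2) Q diag(pi)^(-1/2)``
    is symmetric; its eigendecomposition gives numerically stable
    ``P(d) = exp(Q d)`` for any distance ``d``.
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray):
        s = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if pi.shape != (20,) or not math.isclose(pi.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("frequencies must be a 20-vector summing to 1")
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise to one expected substitution per site per unit time
        rate = -np.dot(pi, np.diag(q))
        q /= rate
        self.pi = pi
        self.q = q
        sq = np.sqrt(pi)
        sym = (q * sq[:, None]) / sq[None, :]
        sym = (sym + sym.T) / 2.0
        eigval, eigvec = np.linalg.eigh(sym)
        self._eigval = eigval
        self._left = eigvec / sq[:, None] * 1.0
        self._right = (eigvec * sq[:, None]).T

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(d): probability of observing residue j after distance d given i."""
        if d < 0:
            raise ValueError("distance must be non-negative")
        p = (self._left * np.exp(self._eigval * d)) @ self._right
        return np.clip(p, 1e-300, None)

    @classmethod
    def load(cls) -> "JTTModel":
        """Load the packaged Jones et al. (1992) matrix, verifying its checksum."""
        data = resources.files("mipclass.data").joinpath(_JTT_FILE).read_bytes()
        digest = hashlib.sha256(data).hexdigest()
        if digest != _JTT_SHA256:
            raise RuntimeError(f"JTT data file checksum mismatch: {digest}")
        rows = [
            [float(tok) for tok in line.split()]
            for line in data.decode().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        tri, freqs = rows[:19], np.array(rows[19])
        s = np.zeros((20, 20))
        for i, row in enumerate(tri, start=1):
            s[i, : len(row)] = row
        s = s + s.T
        return cls(s, freqs)


_MODEL: JTTModel | None = None


def default_model() -> JTTModel:
    global _MODEL
    if _MODEL is None:
        _MODEL = JTTModel.load()
    return _MODEL


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: equal-length gapped rows keyed by id."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def codes(self) -> np.ndarray:
        """Integer-coded matrix (gap and any non-standard letter -> GAP_CODE)."""
        out = np.full((len(self.rows), self.n_cols), GAP_CODE, dtype=np.int8)
        for i, row in enumerate(self.rows):
            out[i] = [_AA_INDEX.get(c, GAP_CODE) for c in row]
        return out

    def select_columns(self, cols: np.ndarray) -> "Msa":
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return Msa(self.ids, rows)

    @classmethod
    def from_file(cls, path, fmt: str = "fasta") -> "Msa":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), fmt)
        return cls(tuple(rec.id for rec in aln), tuple(str(rec.seq).upper() for rec in aln))

    def write(self, path, fmt: str = "fasta") -> None:
        from Bio import AlignIO
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        aln = MultipleSeqAlignment(
            [SeqRecord(Seq(r), id=i, description="") for i, r in zip(self.ids, self.rows)]
        )
        AlignIO.write(aln, str(path), fmt)


def trim_msa(msa: Msa, terminal_gap_fraction: float = 0.5) -> Msa:
    """Remove non-informative terminal columns from an alignment.

    Maximal runs of leading and trailing columns whose gap fraction exceeds
    ``terminal_gap_fraction`` are removed; internal columns are never touched.
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    n = len(msa.rows)
    gap_frac = [sum(r[c] == GAP for r in msa.rows) / n for c in range(msa.n_cols)]
    lo = 0
    while lo < msa.n_cols and gap_frac[lo] > terminal_gap_fraction:
        lo += 1
    hi = msa.n_cols
    while hi > lo and gap_frac[hi - 1] > terminal_gap_fraction:
        hi -= 1
    if lo >= hi:
        raise ValueError(
            f"trimming removed every column at terminal gap fraction {terminal_gap_fraction}"
        )
    if lo == 0 and hi == msa.n_cols:
        return msa
    return Msa(msa.ids, tuple(r[lo:hi] for r in msa.rows))


# ---------------------------------------------------------------------------
# JTT maximum-likelihood distances


def _pair_counts(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """20x20 matrix of residue-pair counts over shared ungapped columns."""
    mask = (codes_a != GAP_CODE) & (codes_b != GAP_CODE)
    a, b = codes_a[mask], codes_b[mask]
    counts = np.bincount(a.astype(np.int64) * 20 + b, minlength=400)
    return counts.reshape(20, 20).astype(float)


def _ml_distance_from_counts(
    counts: np.ndarray, model: JTTModel, d_max: float, tol: float
) -> tuple[float, bool]:
    total = counts.sum()
    if total == 0:
        raise ValueError("no shared ungapped columns between rows")
    if np.trace(counts) == total:
        return 0.0, False
    nonzero = counts > 0
    cvals = counts[nonzero]

    def neg_loglik(d: float) -> float:
        p = model.transition_matrix(d)
        return -float(np.dot(cvals, np.log(p[nonzero])))

    res = minimize_scalar(neg_loglik, bounds=(0.0, d_max), method="bounded", options={"xatol": tol})
    d = float(res.x)
    saturated = d > d_max - 10 * tol
    if saturated:
        d = d_max
    return d, saturated


def jtt_distance(
    row_a: str,
    row_b: str,
    model: JTTModel | None = None,
    d_max: float = 10.0,
    tol: float = 1e-6,
) -> float:
    """Maximum-likelihood JTT distance between two gapped rows.

    Uses pairwise deletion: only columns ungapped in both rows contribute.
    The likelihood ``sum over sites of log(pi_a * P(a->b | d))`` is maximised
    over ``d`` in ``[0, d_max]`` by bounded 1-D search to the given tolerance;
    a fit hitting the bound is reported capped at ``d_max``.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    model = model or default_model()
    code = lambda r: np.array([_AA_INDEX.get(c, GAP_CODE) for c in r], dtype=np.int8)
    d, _ = _ml_distance_from_counts(_pair_counts(code(row_a), code(row_b)), model, d_max, tol)
    return d


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray
    saturated_pairs: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distances")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("non-zero diagonal")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in self.matrix[i]) + "\n")


def jtt_distance_matrix(
    msa: Msa,
    model: JTTModel | None = None,
    d_max: float = 10.0,
    tol: float = 1e-6,
    gap_mode: str = "pairwise",
) -> DistanceMatrix:
    """All pairwise JTT ML distances of an alignment.

    ``gap_mode="pairwise"`` (default) uses, for each pair, the columns
    ungapped in both rows; ``"complete"`` first drops every column with any
    gap and uses the same column set for all pairs.
    """
    if gap_mode not in ("pairwise", "complete"):
        raise ValueError(f"gap_mode must be 'pairwise' or 'complete', got {gap_mode!r}")
    model = model or default_model()
    codes = msa.codes()
    if gap_mode == "complete":
        keep = np.all(codes != GAP_CODE, axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed every column")
        codes = codes[:, keep]
    n = len(msa.ids)
    m = np.zeros((n, n))
    saturated = set()
    for i in range(n):
        for j in range(i + 1, n):
            d, sat = _ml_distance_from_counts(
                _pair_counts(codes[i], codes[j]), model, d_max, tol
            )
            m[i, j] = m[j, i] = d
            if sat:
                saturated.add((msa.ids[i], msa.ids[j]))
    return DistanceMatrix(msa.ids, m, frozenset(saturated))


# ---------------------------------------------------------------------------
# Neighbour joining


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    """An unrooted tree stored with a basal multifurcation at ``root``."""

    root: TreeNode

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.root.leaves())

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial leaf bipartitions, one per internal edge.

        Each bipartition is keyed by the leaf set below the child node of
        the edge (the complement is implied).
        """
        out: dict[frozenset[str], TreeNode] = {}
        all_leaves = self.leaf_names
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            below = frozenset(l.name for l in node.leaves())
            if 2 <= len(below) <= len(all_leaves) - 2:
                out[below] = node
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.9f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{int(round(node.support))}"
            return f"({inner}){label}:{node.length:.9f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


_NEWICK_TOKEN = re.compile(r"\(|\)|,|;|:[-+0-9.eE]+|[^():,;\s]+")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Internal node labels are interpreted as bootstrap supports (percent);
    branch lengths follow ':'.
    """
    pos = 0
    text = text.strip()

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
            # optional internal label = support
            m = re.match(r"[^():,;]+", text[pos:])
            if m:
                label = m.group(0)
                pos += len(label)
                if ":" not in label:
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
        m = re.match(r"[^():,;]+", text[pos:])
        if m and node.is_leaf:
            node.name = m.group(0)
            pos += len(m.group(0))
        if pos < len(text) and text[pos] == ":":
            m = re.match(r":([-+0-9.eE]+)", text[pos:])
            node.length = float(m.group(1))
            pos += len(m.group(0))
        return node

    root = parse_node()
    if pos < len(text) and text[pos] == ";":
        pos += 1
    return PhyloTree(root)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining with the Studier-Keppler Q-criterion.

    Ties in Q are broken by the lexicographically smallest pair of cluster
    representative ids (the smallest leaf id in each cluster). Negative
    intermediate branch lengths are clamped to zero with the difference
    transferred to the sibling edge, preserving the joined pair's distance.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    d = {}
    nodes: dict[str, TreeNode] = {}
    reps: dict[str, str] = {}
    active = list(dm.ids)
    for i, a in enumerate(dm.ids):
        nodes[a] = TreeNode(name=a)
        reps[a] = a
        for j, b in enumerate(dm.ids):
            d[(a, b)] = float(dm.matrix[i, j])

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                key = tuple(sorted((reps[a], reps[b])))
                cand = (q, key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        va = d[(a, b)] / 2 + (r[a] - r[b]) / (2 * (m - 2))
        vb = d[(a, b)] - va
        if va < 0:
            vb += va
            va = 0.0
        if vb < 0:
            va += vb
            vb = 0.0
        counter += 1
        u = f"__nj{counter}"
        nodes[a].length = va
        nodes[b].length = vb
        nodes[u] = TreeNode(children=[nodes[a], nodes[b]])
        reps[u] = min(reps[a], reps[b])
        for c in active:
            if c in (a, b):
                continue
            duc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
            d[(u, c)] = d[(c, u)] = max(duc, 0.0)
        d[(u, u)] = 0.0
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = active
    va = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2
    vb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2
    vc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
    for node, v in ((a, va), (b, vb), (c, vc)):
        nodes[node].length = max(v, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_supports(
    msa: Msa,
    n_reps: int = 1000,
    seed: int = 0,
    model: JTTModel | None = None,
    d_max: float = 10.0,
    gap_mode: str = "pairwise",
) -> PhyloTree:
    """NJ tree on the full alignment with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement (keeping the
    column count), recomputes JTT distances and the NJ tree; the support of
    an internal edge is the percentage of replicate trees containing the same
    leaf bipartition. Replicates with a degenerate distance matrix (e.g. a
    pair left with no shared columns) are skipped; more than 10% skips is an
    error.
    """
    if len(msa.ids) < 4:
        raise ValueError("bootstrap supports need at least 4 taxa")
    model = model or default_model()
    rng = np.random.default_rng(seed)
    tree = nj_tree(jtt_distance_matrix(msa, model=model, d_max=d_max, gap_mode=gap_mode))
    target = {bp: node for bp, node in tree.bipartitions().items()}
    counts = {bp: 0 for bp in target}
    all_leaves = tree.leaf_names
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rep_msa = msa.select_columns(cols)
        try:
            rep_tree = nj_tree(
                jtt_distance_matrix(rep_msa, model=model, d_max=d_max, gap_mode=gap_mode)
            )
        except ValueError:
            skipped += 1
            continue
        rep_bips = set(rep_tree.bipartitions())
        for bp in counts:
            if bp in rep_bips or (all_leaves - bp) in rep_bips:
                counts[bp] += 1
    if skipped > 0.1 * n_reps:
        raise RuntimeError(f"{skipped}/{n_reps} bootstrap replicates were degenerate")
    effective = n_reps - skipped
    for bp, node in target.items():
        node.support = 100.0 * counts[bp] / effective
    return tree


def is_monophyletic(tree: PhyloTree, labels) -> tuple[bool, float | None]:
    """Whether some edge bipartition separates exactly ``labels`` from the rest.

    Returns the defining edge's support (percent) when available.
    """
    labels = frozenset(labels)
    leaves = tree.leaf_names
    unknown = labels - leaves
    if unknown:
        raise ValueError(f"unknown leaf label(s): {sorted(unknown)}")
    if not 2 <= len(labels) < len(leaves):
        raise ValueError("label set must contain between 2 and n_leaves-1 labels")
    for bp, node in tree.bipartitions().items():
        if bp == labels or (leaves - bp) == labels:
            return True, node.support
    return False, None
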