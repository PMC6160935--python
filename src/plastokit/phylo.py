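"""Maximum-likelihood tree inference under GTR+I+G for small taxon sets.

The likelihood is computed by Felsenstein pruning with discrete-gamma rate
heterogeneity (equal-probability bins, category-mean rates, 4 categories by
default) mixed with an invariant-sites class.  Because the intended inputs
are a handful of plastid genomes, tree search is exhaustive: every unrooted
topology is enumerated (3 for four taxa, 15 for five, ...) and fitted by
cyclic bounded univariate optimization of branch lengths, exchangeabilities,
base frequencies, gamma shape and the invariant proportion.  Node support
comes from nonparametric bootstrap over alignment columns.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv

from plastokit.codonalign import Supermatrix

STATES = "ACGT"
_IUPAC_MASK = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "-": (1, 1, 1, 1), "?": (1, 1, 1, 1),
}


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class GTRIGModel:
    """GTR+I+G parameters.

    ``exchangeabilities`` order is (AC, AG, AT, CG, CT, GT); GT is fixed to 1
    for identifiability.  The rate matrix is scaled so that one unit of
    branch length equals one expected substitution per variable site.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )
    base_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    p_inv: float = 0.0
    n_cat: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if np.any(self.exchangeabilities < 0) or np.any(self.base_freqs < 0):
            raise ValueError("negative model parameters")
        if abs(self.base_freqs.sum() - 1) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha <= 0 or not (0 <= self.p_inv < 1):
            raise ValueError("alpha must be > 0 and p_inv in [0, 1)")

    def rate_matrix(self) -> np.ndarray:
        s = self.exchangeabilities
        pi = self.base_freqs
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(s, pairs):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def category_rates(self) -> np.ndarray:
        """Mean rate of each of the n_cat equal-probability gamma bins
        (overall mean 1)."""
        a, n = self.alpha, self.n_cat
        if n == 1:
            return np.ones(1)
        # bin edges of Gamma(a, scale=1/a) via the regularized inverse
        edges = gammaincinv(a, np.arange(1, n) / n) / a
        cdf = np.concatenate([[0.0], gammainc(a + 1, edges * a), [1.0]])
        return n * np.diff(cdf)


def _eigendecompose(model: GTRIGModel):
    Q = model.rate_matrix()
    pi = model.base_freqs
    sp = np.sqrt(pi)
    B = (sp[:, None] * Q) / sp[None, :]
    B = 0.5 * (B + B.T)  # symmetrize against round-off
    w, U = np.linalg.eigh(B)
    left = U.T * sp[None, :]
    right = U / sp[:, None]
    return w, right, left


def _transition_matrices(w, right, left, ts: np.ndarray) -> np.ndarray:
    """P(t) for a vector of scaled branch lengths, shape (len(ts), 4, 4)."""
    ew = np.exp(np.outer(ts, w))  # (m, 4)
    return np.einsum("ik,mk,kj->mij", right, ew, left)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.1
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

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self, supports: dict[frozenset, float] | None = None,
               all_names: frozenset | None = None) -> str:
        if all_names is None:
            all_names = frozenset(self.leaf_names())

        def fmt(node: TreeNode, root: bool) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c, False) for c in node.children)
            label = ""
            if supports is not None and not root:
                bp = _canonical_bipartition(frozenset(node.leaf_names()), all_names)
                if bp in supports:
                    label = f"{supports[bp]:.4g}"
            return f"({inner}){label}" + ("" if root else f":{node.length:.6g}")

        return fmt(self, True) + ";"


def parse_newick(text: str) -> TreeNode:
    """Parse a (rooted or unrooted) newick string with branch lengths."""
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick")

    def convert(node) -> TreeNode:
        out = TreeNode(
            name=node.taxon.label.replace(" ", "_") if node.taxon else None,
            length=node.edge.length if node.edge.length is not None else 0.0,
            children=[convert(c) for c in node.child_nodes()],
        )
        return out

    return convert(tree.seed_node)


def _canonical_bipartition(side: frozenset, all_names: frozenset) -> frozenset:
    """Canonical form of a bipartition: the side not containing the
    lexicographically smallest taxon."""
    ref = min(all_names)
    return frozenset(all_names - side) if ref in side else frozenset(side)


def bipartitions(root: TreeNode) -> set[frozenset]:
    """Nontrivial bipartitions of an unrooted tree (rooted at a multifurcation)."""
    all_names = frozenset(root.leaf_names())
    out: set[frozenset] = set()
    for node in root.walk():
        if node is root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if 1 < len(side) < len(all_names) - 1:
            out.add(_canonical_bipartition(side, all_names))
    return out


def enumerate_topologies(taxa: list[str]) -> list[TreeNode]:
    """All unrooted topologies over ``taxa`` (3 for four taxa, 15 for five)."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    base = TreeNode(children=[TreeNode(name=t) for t in taxa[:3]])
    trees = [base]
    for taxon in taxa[3:]:
        nxt: list[TreeNode] = []
        for tree in trees:
            edges = [n for n in tree.walk() if n is not tree]
            for i in range(len(edges)):
                clone = copy.deepcopy(tree)
                target = [n for n in clone.walk() if n is not clone][i]
                _insert_on_edge(clone, target, taxon)
                nxt.append(clone)
        trees = nxt
    return trees


def _insert_on_edge(root: TreeNode, target: TreeNode, taxon: str) -> None:
    parent = next(n for n in root.walk() if target in n.children)
    idx = parent.children.index(target)
    new_internal = TreeNode(children=[target, TreeNode(name=taxon)])
    parent.children[idx] = new_internal


# ---------------------------------------------------------------------------
# site patterns
# ---------------------------------------------------------------------------


@dataclass
class SitePatterns:
    taxa: list[str]
    masks: np.ndarray  # (n_taxa, n_patterns, 4) partial likelihoods at leaves
    counts: np.ndarray  # (n_patterns,)

    @property
    def length(self) -> int:
        return int(self.counts.sum())


def compress_patterns(matrix: Supermatrix) -> SitePatterns:
    """Collapse alignment columns to unique site patterns with counts; the
    likelihood over patterns equals the likelihood over sites."""
    if not matrix.rows or not matrix.rows[0]:
        raise ValueError("empty alignment")
    arr = np.array([list(r.upper()) for r in matrix.rows])
    cols, counts = np.unique(arr, axis=1, return_counts=True)
    n_taxa, n_pat = cols.shape
    masks = np.empty((n_taxa, n_pat, 4))
    for t in range(n_taxa):
        for p in range(n_pat):
            masks[t, p] = _IUPAC_MASK.get(cols[t, p], (1, 1, 1, 1))
    return SitePatterns(list(matrix.taxa), masks, counts.astype(float))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def log_likelihood(
    tree: TreeNode,
    model: GTRIGModel,
    patterns: SitePatterns,
    _decomp=None,
) -> float:
    """Felsenstein-pruning log-likelihood under GTR+I+G.

    Per-site likelihood = p_inv * I(site compatible with being constant) *
    pi(base) + (1 - p_inv) * mean over gamma categories; gaps and ambiguities
    contribute partial likelihood 1 over their compatible states.
    """
    pi = model.base_freqs
    if _decomp is None:
        rates = model.category_rates()
        w, right, left = _eigendecompose(model)
    else:
        rates, w, right, left = _decomp
    leaf_index = {t: i for i, t in enumerate(patterns.taxa)}
    n_pat = patterns.masks.shape[1]
    n_cat = len(rates)

    def cond(node: TreeNode) -> np.ndarray:  # (n_cat, n_pat, 4)
        if node.is_leaf:
            m = patterns.masks[leaf_index[node.name]]
            return np.broadcast_to(m, (n_cat, n_pat, 4))
        L = np.ones((n_cat, n_pat, 4))
        for child in node.children:
            P = _transition_matrices(w, right, left, rates * child.length)
            Lc = cond(child)
            L = L * np.einsum("cij,cpj->cpi", P, Lc)
        return L

    L_root = cond(tree)
    cat_site = np.einsum("cpi,i->cp", L_root, pi)
    var_site = cat_site.mean(axis=0)
    inv_mask = patterns.masks.prod(axis=0)  # (n_pat, 4)
    inv_site = inv_mask @ pi
    site = model.p_inv * inv_site + (1 - model.p_inv) * var_site
    if not np.all(np.isfinite(site)):
        raise FloatingPointError("non-finite site likelihood")
    return float(patterns.counts @ np.log(np.maximum(site, 1e-300)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    tree: TreeNode
    model: GTRIGModel
    lnL: float
    converged: bool = True
    supports: dict[frozenset, float] | None = None


def empirical_base_freqs(patterns: SitePatterns) -> np.ndarray:
    masks = patterns.masks
    unambiguous = masks.sum(axis=2) == 1
    counts = np.zeros(4)
    for t in range(masks.shape[0]):
        sel = unambiguous[t]
        counts += (masks[t, sel] * patterns.counts[sel, None]).sum(axis=0)
    total = counts.sum()
    return counts / total if total else np.full(4, 0.25)


def fit(
    tree: TreeNode,
    patterns: SitePatterns,
    model: GTRIGModel | None = None,
    optimize_model: bool = True,
    tol: float = 1e-6,
    max_rounds: int = 5,
) -> FitResult:
    """Fit branch lengths and (optionally) GTR+I+G parameters on a fixed
    topology by joint bounded quasi-Newton (L-BFGS-B) optimization of the
    log branch lengths and the ten free model parameters (five
    exchangeabilities, three frequency logits, gamma shape, invariant
    proportion), restarted until the log-likelihood improves by less than
    ``tol``.  Deterministic for a given input; the tree is modified in
    place."""
    from scipy.optimize import minimize

    if model is None:
        model = GTRIGModel(base_freqs=empirical_base_freqs(patterns), p_inv=0.1)
    branches = [n for n in tree.walk() if n is not tree]
    n_bl = len(branches)

    # parameter vector: log branch lengths, then (if optimize_model)
    # log10 exchangeabilities, frequency logits, log10 alpha, p_inv
    x_bl = np.log(np.clip([b.length for b in branches], 1e-9, 5.0))
    bounds: list[tuple[float, float]] = [(np.log(1e-9), np.log(5.0))] * n_bl
    if optimize_model:
        x_model = np.concatenate([
            np.log10(np.clip(model.exchangeabilities[:5], 1e-3, 1e3)),
            np.log(np.clip(model.base_freqs[:3], 1e-6, 1)
                   / max(model.base_freqs[3], 1e-6)),
            [np.log10(model.alpha)],
            [model.p_inv],
        ])
        bounds += [(-3, 3)] * 5 + [(-6, 6)] * 3 + [(-1.7, 1.7), (0.0, 0.95)]
        x0 = np.concatenate([x_bl, x_model])
    else:
        x0 = x_bl

    def unpack_model(v: np.ndarray) -> GTRIGModel:
        if not optimize_model:
            return model
        exch = np.append(10 ** v[n_bl : n_bl + 5], 1.0)
        logits = np.append(v[n_bl + 5 : n_bl + 8], 0.0)
        freqs = np.exp(logits - logits.max())
        freqs /= freqs.sum()
        return GTRIGModel(exch, freqs, 10 ** v[n_bl + 8], v[n_bl + 9], model.n_cat)

    decomp_cache: dict[bytes, tuple] = {}

    def neg(v: np.ndarray) -> float:
        for b, u in zip(branches, v[:n_bl]):
            b.length = float(np.exp(u))
        m = unpack_model(v)
        key = v[n_bl:].tobytes()
        decomp = decomp_cache.get(key)
        if decomp is None:
            decomp = (m.category_rates(), *_eigendecompose(m))
            if len(decomp_cache) > 64:
                decomp_cache.clear()
            decomp_cache[key] = decomp
        return -log_likelihood(tree, m, patterns, _decomp=decomp)

    best = -neg(x0)
    x = x0
    converged = False
    for _restart in range(max_rounds):
        res = minimize(neg, x, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
        x = res.x
        now = -res.fun
        if now - best < tol:
            best = max(now, best)
            converged = True
            break
        best = now
    final = -neg(x)  # re-apply the best vector to the tree
    return FitResult(tree, unpack_model(x), final, converged)


def ml_search(
    matrix: Supermatrix,
    max_taxa_exhaustive: int = 8,
    optimize_model: bool = True,
    model: GTRIGModel | None = None,
    tol: float = 1e-6,
) -> FitResult:
    """Exhaustive ML topology search: every unrooted topology is fitted and
    the best log-likelihood wins (ties broken by enumeration order)."""
    if len(matrix.taxa) < 4:
        raise ValueError("ml_search requires at least 4 taxa")
    if len(matrix.taxa) > max_taxa_exhaustive:
        raise ValueError(
            f"{len(matrix.taxa)} taxa exceed the exhaustive-search limit "
            f"({max_taxa_exhaustive}); reduce the taxon set"
        )
    patterns = compress_patterns(matrix)
    best: FitResult | None = None
    for topo in enumerate_topologies(list(matrix.taxa)):
        res = fit(topo, patterns,
                  model=copy.deepcopy(model), optimize_model=optimize_model, tol=tol)
        if best is None or res.lnL > best.lnL + 1e-9:
            best = res
    return best


def bootstrap(
    matrix: Supermatrix,
    best: FitResult | None = None,
    n_replicates: int = 1000,
    seed: int | None = None,
    optimize_model: bool = True,
    tol: float = 1e-4,
) -> dict[frozenset, float]:
    """Nonparametric bootstrap: columns resampled with replacement to the
    original length, ML search per replicate, support = percentage of
    replicates whose best tree contains each bipartition of ``best``'s tree.

    With ``optimize_model=False`` the model parameters of ``best`` are fixed
    and only branch lengths are refitted per replicate (fast mode)."""
    rng = np.random.default_rng(seed)
    if best is None:
        best = ml_search(matrix, optimize_model=optimize_model)
    target = bipartitions(best.tree)
    hits = {bp: 0 for bp in target}
    arr = np.array([list(r) for r in matrix.rows])
    L = arr.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        rows = ["".join(r) for r in arr[:, idx]]
        rep = Supermatrix(matrix.taxa, rows, [("all", 0, L)])
        res = ml_search(
            rep,
            optimize_model=optimize_model,
            model=best.model,  # warm start; refitted unless optimize_model=False
            tol=tol,
        )
        rep_bps = bipartitions(res.tree)
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
    supports = {bp: 100.0 * n / n_replicates for bp, n in hits.items()}
    best.supports = supports
    return supports


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_result(
    fitres: FitResult,
    newick_path=None,
    nexus_path=None,
    params_path=None,
) -> None:
    """Write the fitted tree as newick (supports as internal labels), a NEXUS
    trees block, and a parameter table (lnL, alpha, p_inv, frequencies)."""
    nwk = fitres.tree.newick(supports=fitres.supports)
    if newick_path:
        with open(newick_path, "w") as fh:
            fh.write(nwk + "\n")
    if nexus_path:
        with open(nexus_path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TREES;\n")
            fh.write(f"  TREE best_ml = {nwk}\n")
            fh.write("END;\n")
    if params_path:
        m = fitres.model
        with open(params_path, "w") as fh:
            fh.write("parameter\tvalue\n")
            fh.write(f"lnL\t{fitres.lnL:.6f}\n")
            fh.write(f"alpha\t{m.alpha:.6f}\n")
            fh.write(f"p_inv\t{m.p_inv:.6f}\n")
            for base, f in zip(STATES, m.base_freqs):
                fh.write(f"freq_{base}\t{f:.6f}\n")
            for name, v in zip(("AC", "AG", "AT", "CG", "CT", "GT"), m.exchangeabilities):
                fh.write(f"rate_{name}\t{v:.6f}\n")
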