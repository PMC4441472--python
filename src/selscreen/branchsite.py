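"""Branch-site test for episodic positive selection (Model A vs its null).

The model mixes four site classes over a codon alignment: class 0 evolves
at 0 < omega0 < 1 everywhere, class 1 at omega = 1 everywhere, and classes
2a/2b switch to omega2 on a single designated foreground branch while
keeping omega0 / 1 on the background.  The null fixes omega2 = 1; twice
the log-likelihood difference is referred to a chi-square with one degree
of freedom.  Candidate sites come from a Bayes Empirical Bayes pass that
integrates the class posteriors over a parameter grid.

Likelihoods are computed by Felsenstein pruning over the 61 sense codons,
with site-pattern compression and one eigendecomposition per omega value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .codon import CODON_INDEX, TransitionKernel, equal_frequencies, f3x4_frequencies, mean_rate
from .io import CodonAlignment, LabeledTree

__all__ = [
    "strip_gap_columns",
    "BranchSiteParams",
    "BranchSiteFit",
    "SiteBEB",
    "PositiveSiteRecord",
    "ScreenThresholds",
    "BranchSiteModel",
    "log_likelihood",
    "fit",
    "fit_gene",
    "lrt_pvalue",
    "bh_fdr",
    "beb_posteriors",
    "screen_genes",
]


class EmptyAlignmentError(ValueError):
    """Raised when gap/ambiguity stripping removes every codon column."""


def strip_gap_columns(aln: CodonAlignment) -> tuple[CodonAlignment, list[int]]:
    """Drop codon columns that are not clean sense codons in every taxon.

    A column is removed if any taxon's codon contains a gap or ambiguous
    base, or encodes a stop (frameshifted tails).  Returns the cleaned
    alignment plus a map from retained (0-based) positions to original
    1-based codon columns.
    """
    n = aln.n_codons
    keep: list[int] = []
    for col in range(1, n + 1):
        if all(c in CODON_INDEX for c in aln.codon_column(col)):
            keep.append(col)
    if not keep:
        raise EmptyAlignmentError("alignment empty after removing gapped/ambiguous columns")
    seqs = ["".join(s[(c - 1) * 3 : c * 3] for c in keep) for s in aln.sequences]
    return CodonAlignment(list(aln.taxa), seqs), keep


@dataclass
class BranchSiteParams:
    kappa: float
    omega0: float
    omega2: float  # fixed at 1.0 under the null
    p0: float
    p1: float
    tree_scale: float = 1.0

    def class_proportions(self) -> np.ndarray:
        rest = max(0.0, 1.0 - self.p0 - self.p1)
        tot = self.p0 + self.p1
        if tot == 0:
            return np.array([0.0, 0.0, rest / 2, rest / 2])
        return np.array([self.p0, self.p1, rest * self.p0 / tot, rest * self.p1 / tot])


@dataclass
class SiteBEB:
    column: int  # 1-based codon column (original coordinates when mapped)
    posterior: float  # P(class 2a or 2b | data)


@dataclass
class BranchSiteFit:
    gene: str
    foreground: str
    lnl_alt: float
    lnl_null: float
    params_alt: BranchSiteParams
    params_null: BranchSiteParams
    lrt_stat: float
    p_value: float
    q_value: float | None = None
    converged: bool = True
    n_codons_clean: int = 0
    column_map: list[int] = field(default_factory=list)


@dataclass
class PositiveSiteRecord:
    """One candidate positively-selected site, with downstream verdicts."""

    gene: str
    foreground: str
    column: int  # 1-based codon column in the ORIGINAL alignment
    residue: str  # foreground taxon's amino acid at the site
    posterior: float
    sp_pass: bool | None = None
    cdna_verdict: str | None = None  # valid | invalid | unmapped


@dataclass
class ScreenThresholds:
    p_value: float = 0.01
    q_value: float = 0.05
    beb_posterior: float = 0.95


def gene_passes(p_value: float, q_value: float | None, thresholds: ScreenThresholds) -> bool:
    """Gene-level pass rule: raw p <= cutoff AND BH q < cutoff (conjunction)."""
    if q_value is None or not np.isfinite(p_value):
        return False
    return p_value <= thresholds.p_value and q_value < thresholds.q_value


class BranchSiteModel:
    """Pruning machinery bound to one cleaned alignment and labeled tree.

    Precomputes site patterns and the traversal order; evaluates the four
    class-conditional site likelihoods for arbitrary (kappa, omega0,
    omega2, tree scale), which is everything both model fits and the BEB
    pass need.
    """

    #: (background omega, foreground omega) index per site class, into
    #: the (omega0, 1, omega2) triple.
    CLASS_OMEGA_IDX = ((0, 0), (1, 1), (0, 2), (1, 2))

    def __init__(self, aln: CodonAlignment, tree: LabeledTree, codon_freq: str = "f3x4"):
        missing = set(tree.leaf_names()) - set(aln.taxa)
        if missing:
            raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
        self.aln = aln
        self.tree = tree
        if codon_freq == "f3x4":
            self.pi = f3x4_frequencies(aln.sequences)
        elif codon_freq == "equal":
            self.pi = equal_frequencies()
        else:
            self.pi = np.asarray(codon_freq, dtype=float)

        states = np.array(
            [[CODON_INDEX[s[i : i + 3]] for i in range(0, len(s), 3)] for s in aln.sequences]
        )  # taxa x columns
        cols = states.T
        patterns, inverse, counts = np.unique(cols, axis=0, return_inverse=True, return_counts=True)
        self.pattern_states = patterns.T  # taxa x n_patterns
        self.pattern_of_column = inverse
        self.pattern_weights = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        self.n_columns = cols.shape[0]
        self.taxon_row = {t: i for i, t in enumerate(aln.taxa)}

        # postorder traversal: (children descriptors per internal node)
        fg_node = tree.foreground_node()
        self._postorder: list[tuple[int, list[tuple[int | None, int | None, int, bool]]]] = []
        self._node_slot: dict[int, int] = {}
        edge_lengths: list[float] = []
        fg_edge_pos: dict[int, int] = {}
        slot = 0
        for node in tree.tree.postorder_node_iter():
            if node.is_leaf():
                continue
            children = []
            for ch in node.child_nodes():
                edge_idx = len(edge_lengths)
                edge_lengths.append(ch.edge.length or 0.0)
                is_fg = ch is fg_node
                if is_fg:
                    fg_edge_pos[edge_idx] = len(fg_edge_pos)
                if ch.is_leaf():
                    children.append((None, self.taxon_row[ch.taxon.label], edge_idx, is_fg))
                else:
                    children.append((self._node_slot[id(ch)], None, edge_idx, is_fg))
            self._node_slot[id(node)] = slot
            self._postorder.append((slot, children))
            slot += 1
        self._root_slot = self._node_slot[id(tree.tree.seed_node)]
        self._edge_lengths = np.array(edge_lengths)
        self._fg_edge_pos = fg_edge_pos
        self._fg_lengths = self._edge_lengths[sorted(fg_edge_pos)] if fg_edge_pos else np.empty(0)
        # per-site likelihoods stay far above double underflow for small
        # trees; per-node rescaling only pays for itself on big ones
        self._rescale = aln.n_taxa > 14
        self._kernel_cache: dict[tuple[float, float], TransitionKernel] = {}
        self._class_cache: dict[tuple[float, float, float, float], np.ndarray] = {}
        self._rate_cache: dict = {}

    def _kernel(self, kappa: float, omega: float) -> TransitionKernel:
        key = (kappa, omega)
        if key not in self._kernel_cache:
            if len(self._kernel_cache) > 64:
                self._kernel_cache.clear()
            self._kernel_cache[key] = TransitionKernel(kappa, omega, self.pi, normalize=False)
        return self._kernel_cache[key]

    def _rate(self, kappa: float, omega: float) -> float:
        key = ("rate", kappa, omega)
        if key not in self._rate_cache:
            if len(self._rate_cache) > 256:
                self._rate_cache.clear()
            self._rate_cache[key] = mean_rate(kappa, omega, self.pi)
        return self._rate_cache[key]

    def mixture_rate(self, params: BranchSiteParams) -> float:
        """Shared time-scale factor: background-mixture expected flux.

        Branch lengths divided by this factor read as expected
        substitutions per codon under the background site-class mixture;
        the same convention the simulator uses.
        """
        props = params.class_proportions()
        w0 = props[0] + props[2]
        return w0 * self._rate(params.kappa, params.omega0) + (1 - w0) * self._rate(params.kappa, 1.0)

    def _prune(
        self,
        kappa: float,
        bg_omega: float,
        fg_omega: float,
        scale: float,
        pcache: dict | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Site-pattern likelihoods for one (background, foreground) omega pair."""
        pcache = {} if pcache is None else pcache
        key_bg = ("bg", kappa, bg_omega, scale)
        if key_bg not in pcache:
            pcache[key_bg] = self._kernel(kappa, bg_omega).probability_matrices(self._edge_lengths * scale)
        bg_ps = pcache[key_bg]
        key_fg = ("fg", kappa, fg_omega, scale)
        if key_fg not in pcache:
            pcache[key_fg] = self._kernel(kappa, fg_omega).probability_matrices(self._fg_lengths * scale)
        fg_ps = pcache[key_fg]
        partials = [None] * len(self._postorder)
        log_scale = np.zeros(self.n_patterns)
        for slot, children in self._postorder:
            acc = None
            for child_slot, leaf_row, edge_idx, is_fg in children:
                p = fg_ps[self._fg_edge_pos[edge_idx]] if is_fg else bg_ps[edge_idx]
                if leaf_row is not None:
                    term = p[:, self.pattern_states[leaf_row]].T  # n_patterns x 61
                else:
                    term = partials[child_slot] @ p.T
                acc = term if acc is None else acc * term
            if self._rescale:
                peak = acc.max(axis=1)
                low = peak < 1e-200
                if low.any():
                    safe = np.where(peak > 0, peak, 1.0)
                    acc = acc / np.where(low, safe, 1.0)[:, None]
                    log_scale += np.where(low & (peak > 0), np.log(safe), 0.0)
            partials[slot] = acc
        site_lik = partials[self._root_slot] @ self.pi
        return site_lik, log_scale

    def class_site_loglikelihoods(self, kappa: float, omega0: float, omega2: float, scale: float = 1.0) -> np.ndarray:
        """log site-pattern likelihoods, one row per site class (4 x n_patterns)."""
        ckey = (kappa, omega0, omega2, scale)
        cached = self._class_cache.get(ckey)
        if cached is not None:
            return cached
        omegas = (omega0, 1.0, omega2)
        out = np.empty((4, self.n_patterns))
        cache: dict[tuple[int, int], np.ndarray] = {}
        pcache: dict = {}
        for c, (bg_i, fg_i) in enumerate(self.CLASS_OMEGA_IDX):
            key = (bg_i, fg_i)
            if key not in cache:
                lik, log_scale = self._prune(kappa, omegas[bg_i], omegas[fg_i], scale, pcache)
                with np.errstate(divide="ignore"):
                    cache[key] = np.log(lik) + log_scale
            out[c] = cache[key]
        if len(self._class_cache) > 32:
            self._class_cache.clear()
        self._class_cache[ckey] = out
        return out

    def log_likelihood(self, params: BranchSiteParams) -> float:
        scale_eff = params.tree_scale / self.mixture_rate(params)
        logl_c = self.class_site_loglikelihoods(params.kappa, params.omega0, params.omega2, scale_eff)
        props = params.class_proportions()
        m = logl_c.max(axis=0)
        mix = np.log(np.maximum(props @ np.exp(logl_c - m), 1e-300)) + m
        value = float(self.pattern_weights @ mix)
        if not np.isfinite(value):
            bad = int(np.argmin(mix))
            raise FloatingPointError(f"non-finite likelihood at site pattern {bad}")
        return value


def log_likelihood(aln: CodonAlignment, tree: LabeledTree, params: BranchSiteParams, model: str = "alt", codon_freq: str = "f3x4") -> float:
    """Model A mixture log-likelihood; the null forces omega2 = 1."""
    if model not in ("alt", "null"):
        raise ValueError("model must be 'alt' or 'null'")
    if model == "null" and params.omega2 != 1.0:
        params = BranchSiteParams(params.kappa, params.omega0, 1.0, params.p0, params.p1, params.tree_scale)
    return BranchSiteModel(aln, tree, codon_freq).log_likelihood(params)


_OMEGA0_LO, _OMEGA0_HI = 1e-6, 1.0 - 1e-9
_OMEGA2_HI = 999.0


def _unpack(x: np.ndarray, model: str, estimate_scale: bool, fixed_scale: float) -> BranchSiteParams:
    kappa = np.exp(x[0])
    omega0 = _OMEGA0_LO + (_OMEGA0_HI - _OMEGA0_LO) / (1.0 + np.exp(-x[1]))
    m = max(0.0, x[2], x[3])  # stabilized softmax over (rest, p0, p1)
    e0, e2, e3 = np.exp(-m), np.exp(x[2] - m), np.exp(x[3] - m)
    tot = e0 + e2 + e3
    p0, p1 = e2 / tot, e3 / tot
    i = 4
    if model == "alt":
        omega2 = 1.0 + (_OMEGA2_HI - 1.0) / (1.0 + np.exp(-x[i]))
        i += 1
    else:
        omega2 = 1.0
    scale = np.exp(x[i]) if estimate_scale else fixed_scale
    return BranchSiteParams(kappa, omega0, omega2, p0, p1, scale)


_DEFAULT_START = BranchSiteParams(kappa=2.0, omega0=0.5, omega2=2.0, p0=0.6, p1=0.25, tree_scale=1.0)


def _logit(y: float) -> float:
    y = min(max(y, 1e-9), 1 - 1e-9)
    return float(np.log(y / (1 - y)))


def _pack(params: BranchSiteParams, model: str, estimate_scale: bool) -> np.ndarray:
    rest = max(1e-9, 1.0 - params.p0 - params.p1)
    x = [
        np.log(params.kappa),
        _logit((params.omega0 - _OMEGA0_LO) / (_OMEGA0_HI - _OMEGA0_LO)),
        np.log(max(params.p0, 1e-9) / rest),
        np.log(max(params.p1, 1e-9) / rest),
    ]
    if model == "alt":
        x.append(_logit((max(params.omega2, 1.0 + 1e-6) - 1.0) / (_OMEGA2_HI - 1.0)))
    if estimate_scale:
        x.append(np.log(params.tree_scale))
    return np.array(x)


def fit(
    aln: CodonAlignment,
    tree: LabeledTree,
    model: str = "alt",
    codon_freq: str = "f3x4",
    n_starts: int = 3,
    seed: int = 0,
    estimate_scale: bool = False,
    fixed_scale: float = 1.0,
    engine: BranchSiteModel | None = None,
    start_params: BranchSiteParams | None = None,
) -> tuple[float, BranchSiteParams, bool]:
    """Maximize one side of the branch-site test.

    Parameters are optimized in unconstrained space (log kappa, logit
    omega0 within (1e-6, 1), softmax class proportions, omega2 in
    [1, 999] under the alternative, optionally a log tree-scale) with
    L-BFGS-B from ``n_starts`` seeded starting points.  Returns
    (lnL, parameters, converged).
    """
    if model not in ("alt", "null"):
        raise ValueError("model must be 'alt' or 'null'")
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    engine = engine or BranchSiteModel(aln, tree, codon_freq)

    def objective(x: np.ndarray) -> float:
        try:
            return -engine.log_likelihood(_unpack(x, model, estimate_scale, fixed_scale))
        except FloatingPointError:
            return 1e12

    base = _pack(start_params or _DEFAULT_START, model, estimate_scale)

    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    # coarse pass over every start, then a strict polish of the winner
    for start in range(max(1, n_starts)):
        x0 = base if start == 0 else base + rng.normal(0.0, 0.6, size=base.size)
        res = minimize(objective, x0, method="L-BFGS-B", options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-6})
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    best = minimize(objective, best.x, method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    params = _unpack(best.x, model, estimate_scale, fixed_scale)
    return -float(best.fun), params, n_ok > 0


def lrt_pvalue(lnl_alt: float, lnl_null: float, tol: float = 1e-6) -> tuple[float, float]:
    """LRT statistic 2(lnL_alt - lnL_null) and its chi-square(1) p-value.

    Small negative statistics (optimizer noise) are clamped to zero;
    larger ones indicate a failed alternative fit and raise.
    """
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < -2 * tol:
        raise ValueError(f"lnL_alt < lnL_null beyond tolerance (stat={stat:.3g})")
    stat = max(0.0, stat)
    return stat, float(chi2.sf(stat, df=1))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_gene(
    aln: CodonAlignment,
    tree: LabeledTree,
    gene: str = "gene",
    codon_freq: str = "f3x4",
    n_starts: int = 3,
    seed: int = 0,
    estimate_scale: bool = True,
) -> BranchSiteFit:
    """Run both sides of the branch-site test on one gene.

    Gap/ambiguous codon columns are stripped first (the column map is kept
    so sites can be reported in original coordinates).  A tree-wide branch
    length scale is estimated under the null and held fixed for the
    alternative, keeping the two fits on a shared tree.
    """
    clean, column_map = strip_gap_columns(aln)
    engine = BranchSiteModel(clean, tree, codon_freq)
    lnl_null, params_null, ok_null = fit(
        clean, tree, "null", codon_freq, n_starts, seed, estimate_scale=estimate_scale, engine=engine
    )
    warm = BranchSiteParams(
        params_null.kappa, params_null.omega0, 2.0, params_null.p0, params_null.p1, params_null.tree_scale
    )
    lnl_alt, params_alt, ok_alt = fit(
        clean,
        tree,
        "alt",
        codon_freq,
        n_starts,
        seed + 1,
        estimate_scale=False,
        fixed_scale=params_null.tree_scale,
        engine=engine,
        start_params=warm,
    )
    if lnl_alt < lnl_null:  # nested models: alt can always match the null
        lnl_alt = lnl_null
        params_alt = BranchSiteParams(
            params_null.kappa, params_null.omega0, 1.0, params_null.p0, params_null.p1, params_null.tree_scale
        )
    stat, p = lrt_pvalue(lnl_alt, lnl_null)
    return BranchSiteFit(
        gene=gene,
        foreground=tree.foreground,
        lnl_alt=lnl_alt,
        lnl_null=lnl_null,
        params_alt=params_alt,
        params_null=params_null,
        lrt_stat=stat,
        p_value=p,
        converged=ok_null and ok_alt,
        n_codons_clean=clean.n_codons,
        column_map=column_map,
    )


def beb_posteriors(
    aln: CodonAlignment,
    tree: LabeledTree,
    fit_alt: BranchSiteFit | BranchSiteParams,
    codon_freq: str = "f3x4",
    grid_size: int = 10,
    map_columns: bool = True,
) -> list[SiteBEB]:
    """Bayes Empirical Bayes posterior of foreground positive selection.

    Integrates the per-site class posterior over a uniform prior on a
    ``grid_size``-point triangular grid for (p0, p1) and ``grid_size``-point
    grids for omega0 and omega2 in (0,1) and (1, 11], with kappa and the
    tree scale fixed at their MLEs.  Grid points are weighted by the full
    alignment likelihood, then each site's probability of class 2a or 2b
    is averaged under those weights.
    """
    if isinstance(fit_alt, BranchSiteFit):
        if not fit_alt.converged:
            raise ValueError("refusing BEB on an unconverged fit")
        params = fit_alt.params_alt
        clean, column_map = strip_gap_columns(aln)
    else:
        params = fit_alt
        clean, column_map = strip_gap_columns(aln)
    engine = BranchSiteModel(clean, tree, codon_freq)

    d = grid_size
    omega0_grid = (np.arange(d) + 0.5) / d
    omega2_grid = 1.0 + (np.arange(d) + 0.5) * (10.0 / d)
    p_grid = (np.arange(d) + 0.5) / d

    # branch lengths stay fixed at their fitted time scale over the grid
    scale_eff = params.tree_scale / engine.mixture_rate(params)

    # class-conditional log site likelihoods for every needed omega combo
    log_l1 = None
    log_l0 = {}
    log_l2b = {}
    log_l2a = {}
    for w0 in omega0_grid:
        logl = engine.class_site_loglikelihoods(params.kappa, w0, omega2_grid[0], scale_eff)
        log_l0[w0] = logl[0]
        if log_l1 is None:
            log_l1 = logl[1]
        log_l2a[(w0, omega2_grid[0])] = logl[2]
        log_l2b[omega2_grid[0]] = logl[3]
        for w2 in omega2_grid[1:]:
            logl2 = engine.class_site_loglikelihoods(params.kappa, w0, w2, scale_eff)
            log_l2a[(w0, w2)] = logl2[2]
            log_l2b[w2] = logl2[3]

    thetas = []
    for p0 in p_grid:
        for p1 in p_grid:
            if p0 + p1 > 1:
                continue
            props = BranchSiteParams(params.kappa, 0.5, 2.0, p0, p1).class_proportions()
            for w0 in omega0_grid:
                for w2 in omega2_grid:
                    thetas.append((props, w0, w2))

    n_pat = engine.n_patterns
    log_post = np.empty(len(thetas))
    site_pos = np.empty((len(thetas), n_pat))
    for k, (props, w0, w2) in enumerate(thetas):
        logs = np.stack([log_l0[w0], log_l1, log_l2a[(w0, w2)], log_l2b[w2]])
        m = logs.max(axis=0)
        liks = np.exp(logs - m)
        mix = props @ liks
        log_post[k] = float(engine.pattern_weights @ (np.log(np.maximum(mix, 1e-300)) + m))
        site_pos[k] = (props[2] * liks[2] + props[3] * liks[3]) / np.maximum(mix, 1e-300)

    log_post -= log_post.max()
    w = np.exp(log_post)
    w /= w.sum()
    pattern_posterior = w @ site_pos

    out = []
    for col0 in range(engine.n_columns):
        post = float(pattern_posterior[engine.pattern_of_column[col0]])
        column = column_map[col0] if map_columns else col0 + 1
        out.append(SiteBEB(column=column, posterior=min(1.0, post)))
    return out


def screen_genes(
    alignments: dict[str, CodonAlignment],
    trees: "dict[str, LabeledTree] | LabeledTree",
    thresholds: ScreenThresholds | None = None,
    codon_freq: str = "f3x4",
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[list[BranchSiteFit], list[PositiveSiteRecord]]:
    """Branch-site screen over a gene set for one foreground designation.

    Fits every gene, BH-adjusts the p-values across the set, and reports
    BEB sites (posterior > threshold, original coordinates) for genes
    passing both the raw p-value and FDR thresholds.  Per-gene failures
    are recorded as unconverged fits rather than aborting the screen.
    """
    thresholds = thresholds or ScreenThresholds()
    fits: list[BranchSiteFit] = []
    for i, (gene, aln) in enumerate(sorted(alignments.items())):
        tree = trees[gene] if isinstance(trees, dict) else trees
        try:
            fits.append(fit_gene(aln, tree, gene=gene, codon_freq=codon_freq, n_starts=n_starts, seed=seed + 17 * i))
        except (ValueError, RuntimeError, EmptyAlignmentError):
            fits.append(
                BranchSiteFit(
                    gene=gene,
                    foreground=tree.foreground if hasattr(tree, "foreground") else "?",
                    lnl_alt=np.nan,
                    lnl_null=np.nan,
                    params_alt=BranchSiteParams(1, 0.5, 1, 0.5, 0.5),
                    params_null=BranchSiteParams(1, 0.5, 1, 0.5, 0.5),
                    lrt_stat=np.nan,
                    p_value=np.nan,
                    converged=False,
                )
            )

    usable = [f for f in fits if f.converged and np.isfinite(f.p_value)]
    if usable:
        qs = bh_fdr([f.p_value for f in usable])
        for f, q in zip(usable, qs):
            f.q_value = float(q)

    sites: list[PositiveSiteRecord] = []
    for f in usable:
        if not gene_passes(f.p_value, f.q_value, thresholds):
            continue
        aln = alignments[f.gene]
        tree = trees[f.gene] if isinstance(trees, dict) else trees
        for beb in beb_posteriors(aln, tree, f, codon_freq=codon_freq):
            if beb.posterior > thresholds.beb_posterior:
                residue = _foreground_residue(aln, f.foreground, beb.column)
                sites.append(
                    PositiveSiteRecord(
                        gene=f.gene,
                        foreground=f.foreground,
                        column=beb.column,
                        residue=residue,
                        posterior=beb.posterior,
                    )
                )
    return fits, sites


def _foreground_residue(aln: CodonAlignment, foreground: str, column: int) -> str:
    from .codon import translate_codon

    if foreground in aln.taxa:
        return translate_codon(aln.codon(foreground, column))
    return "?"
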