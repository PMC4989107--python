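"""Per-codon likelihood-ratio test of selective constraint.

The model is a GY94-style codon substitution process on the 61 sense codons:
instantaneous rates are zero for multi-nucleotide changes and otherwise
proportional to the target codon's equilibrium frequency pi_j, multiplied by
kappa for transitions and by omega for nonsynonymous changes.  The generator
is normalized so that at omega = 1 branch lengths are expected substitutions
per codon site; varying omega then rescales only the nonsynonymous flow,
anchoring every test to the gene's local synonymous substitution rate.

Per gene, (kappa, omega_g, rho) are estimated once by maximum likelihood
over all codon columns with the query species excluded (masked, to limit
reference bias); rho is a scalar multiplier on the fixed species-tree branch
lengths.  Each queried codon is then tested by comparing the maximized
likelihood with a free site-specific omega (alternative) against omega
fixed at 1 (neutral null), with the query still excluded.  The statistic
D = 2(lnL1 - lnL0) is referred to a chi-squared distribution with one
degree of freedom; a codon yields a deleterious call only when the p-value
clears a Bonferroni-corrected threshold, the site is constrained
(omega_hat < 1), and the queried allele pair is novel relative to the other
species (either ref or alt unseen elsewhere in the alignment column).
Codons with fewer than 10 informative species are not tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import codons
from .formats_io import CodonAlignment, Phylogeny

logger = logging.getLogger("delscan")

LOG_FLOOR = -745.0  # ln of the smallest positive double
OMEGA_BOUNDS = (1e-4, 10.0)
DEFAULT_MIN_SPECIES = 10


class GeneFitError(RuntimeError):
    """Gene-level optimization failed; carries the best parameters found."""

    def __init__(self, message: str, params: "CodonModelParams | None" = None):
        super().__init__(message)
        self.params = params


@dataclass
class CodonModelParams:
    """Gene-level substitution model parameters."""

    kappa: float
    omega_g: float
    rho: float
    pi: np.ndarray  # 61 codon equilibrium frequencies
    converged: bool = True
    loglik: float = float("nan")

    def validate(self) -> None:
        if self.kappa <= 0 or self.omega_g < 0 or self.rho < 0:
            raise ValueError("invalid codon model parameters")
        if self.pi.shape != (codons.N_STATES,) or np.any(self.pi < 0):
            raise ValueError("pi must be 61 nonnegative frequencies")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")


@dataclass
class SiteTestResult:
    """Outcome of the constraint test at one codon."""

    codon_index: int
    n_species_informative: int
    lnl0: float = float("nan")
    lnl1: float = float("nan")
    omega_site: float = float("nan")
    statistic: float = float("nan")
    p_value: float = float("nan")
    novel: bool | None = None
    masked: bool = True
    verdict: str = "untested"


# ---------------------------------------------------------------------------
# Rate matrix
# ---------------------------------------------------------------------------

def _unnormalized_rates(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    q = np.where(codons.NEIGHBOR, np.broadcast_to(pi, (codons.N_STATES,) * 2), 0.0).copy()
    q[codons.IS_TRANSITION] *= kappa
    q[codons.IS_NONSYN] *= omega
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def build_rate_matrix(params: CodonModelParams, omega: float) -> np.ndarray:
    """61x61 generator at the given site omega.

    Normalized by the mean rate at omega = 1 (same kappa and pi), so branch
    lengths are expected substitutions per codon site under neutrality and
    the synonymous rate does not change with omega.
    """
    params.validate()
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    pi = params.pi
    neutral = _unnormalized_rates(params.kappa, 1.0, pi)
    scale = -float(pi @ np.diag(neutral))
    if scale <= 0:
        raise ValueError("degenerate rate matrix: zero mean rate")
    return _unnormalized_rates(params.kappa, omega, pi) / scale


def _eig_transition_factory(params: CodonModelParams, omega: float):
    """Return P(t) via eigendecomposition of the reversible-symmetrized Q."""
    q = build_rate_matrix(params, omega)
    pi = params.pi
    # guard: states with pi == 0 cannot be observed; caller checks usage
    sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
    sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
    sym = 0.5 * (sym + sym.T)
    w, u = np.linalg.eigh(sym)
    left = u / sqrt_pi[:, None]   # rows scaled by 1/sqrt(pi)
    right = u.T * sqrt_pi[None, :]

    def pmat(t: float) -> np.ndarray:
        if t == 0.0:
            return np.eye(codons.N_STATES)
        p = (left * np.exp(w * t)) @ right
        np.clip(p, 0.0, None, out=p)
        return p

    return pmat


# ---------------------------------------------------------------------------
# Tree indexing and pruning
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Postorder array view of a phylogeny bound to alignment rows.

    Tips absent from the alignment, excluded, or missing at a column enter
    the pruning with all-ones partials (marginalized out).
    """

    def __init__(self, phylo: Phylogeny, aln: CodonAlignment, exclude: frozenset[str]):
        missing_from_tree = set(aln.taxa) - set(phylo.tip_labels)
        if missing_from_tree:
            raise ValueError(
                f"alignment taxa not in tree: {sorted(missing_from_tree)}"
            )
        row_of = {t: i for i, t in enumerate(aln.taxa)}
        nodes = list(phylo.tree.postorder_node_iter())
        pos = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children: list[list[tuple[int, int]]] = []  # (child_pos, edge_id)
        self.taxon_row: list[int] = []
        self.edge_lengths: list[float] = []
        for node in nodes:
            kids = []
            for child in node.child_nodes():
                edge_id = len(self.edge_lengths)
                self.edge_lengths.append(float(child.edge.length or 0.0))
                kids.append((pos[id(child)], edge_id))
            self.children.append(kids)
            if not node.child_nodes():
                label = node.taxon.label if node.taxon else None
                if label in row_of and label not in exclude:
                    self.taxon_row.append(row_of[label])
                else:
                    self.taxon_row.append(-1)
            else:
                self.taxon_row.append(-1)
        self.edge_lengths = np.asarray(self.edge_lengths)
        self.root = self.n_nodes - 1

    def data_rows(self) -> list[int]:
        return [r for r in self.taxon_row if r >= 0]


def _pruning_loglik(
    index: _TreeIndex,
    matrix: np.ndarray,
    columns: np.ndarray,
    pmats: list[np.ndarray],
    pi: np.ndarray,
) -> np.ndarray:
    """Felsenstein pruning over codon columns; returns lnL per column."""
    n = len(columns)
    nstate = codons.N_STATES
    partials: list[np.ndarray | None] = [None] * index.n_nodes
    logscale = np.zeros(n)
    for node in range(index.n_nodes):
        kids = index.children[node]
        if not kids:
            row = index.taxon_row[node]
            part = np.ones((n, nstate))
            if row >= 0:
                states = matrix[row, columns]
                obs = states != codons.MISSING
                if obs.any():
                    part[obs] = 0.0
                    part[np.nonzero(obs)[0], states[obs]] = 1.0
            partials[node] = part
            continue
        part = np.ones((n, nstate))
        for child_pos, edge_id in kids:
            child_part = partials[child_pos]
            partials[child_pos] = None
            part *= child_part @ pmats[edge_id].T
        mx = part.max(axis=1)
        ok = mx > 0
        scale = np.where(ok, mx, 1.0)
        part /= scale[:, None]
        logscale += np.where(ok, np.log(scale), LOG_FLOOR)
        partials[node] = part
    root_like = partials[index.root] @ pi
    with np.errstate(divide="ignore"):
        lnl = np.log(root_like) + logscale
    return np.maximum(lnl, LOG_FLOOR)


class LikelihoodWorkspace:
    """Caches tree indexing and per-omega transition matrices for one gene."""

    def __init__(
        self,
        aln: CodonAlignment,
        tree: Phylogeny,
        params: CodonModelParams,
        exclude: frozenset[str] = frozenset(),
    ):
        params.validate()
        self.aln = aln
        self.params = params
        self.index = _TreeIndex(tree, aln, exclude)
        observed = aln.matrix[aln.matrix != codons.MISSING]
        if observed.size and np.any(params.pi[observed] == 0):
            raise ValueError("pi assigns zero frequency to an observed codon state")
        self._pmat_cache: dict[float, list[np.ndarray]] = {}

    def pmats(self, omega: float) -> list[np.ndarray]:
        key = float(omega)
        cached = self._pmat_cache.get(key)
        if cached is None:
            factory = _eig_transition_factory(self.params, omega)
            lengths = self.params.rho * self.index.edge_lengths
            cached = [factory(t) for t in lengths]
            if len(self._pmat_cache) > 512:
                # keep the earliest entries: shared optimizer probe points
                for k in list(self._pmat_cache)[64:]:
                    del self._pmat_cache[k]
            self._pmat_cache[key] = cached
        return cached

    def loglik(self, omega: float, columns) -> np.ndarray:
        columns = np.atleast_1d(np.asarray(columns, dtype=np.int64))
        if columns.size and (columns.min() < 0 or columns.max() >= self.aln.n_codons):
            raise IndexError("codon column out of range")
        return _pruning_loglik(
            self.index, self.aln.matrix, columns, self.pmats(omega), self.params.pi
        )


def site_log_likelihood(
    aln: CodonAlignment,
    tree: Phylogeny,
    params: CodonModelParams,
    omega: float,
    codon_index: int,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> float:
    """Pruning log-likelihood of one codon column at the given site omega."""
    exclude = frozenset(exclude)
    ws = LikelihoodWorkspace(aln, tree, params, exclude)
    states = aln.column_states(codon_index)
    informative = [
        t
        for t, s in zip(aln.taxa, states)
        if s != codons.MISSING and t not in exclude
    ]
    if not informative:
        raise ValueError(f"all taxa missing at codon {codon_index}")
    return float(ws.loglik(omega, [codon_index])[0])


# ---------------------------------------------------------------------------
# Gene-level fit
# ---------------------------------------------------------------------------

def f3x4_frequencies(
    aln: CodonAlignment, exclude: frozenset[str] = frozenset(), pseudocount: float = 0.5
) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Counts come from non-missing codons of non-excluded taxa; a small
    pseudocount keeps every sense codon attainable in short alignments.
    The product frequencies are renormalized over the 61 sense codons.
    """
    counts = np.full((3, 4), pseudocount)
    rows = [i for i, t in enumerate(aln.taxa) if t not in exclude]
    for i in rows:
        seq = aln.aligned_seqs[i]
        for c in range(aln.n_codons):
            if aln.matrix[i, c] == codons.MISSING:
                continue
            for k in range(3):
                counts[k, codons.BASE_INDEX[seq[3 * c + k]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, codons.BASE_INDEX[c[0]]]
            * freqs[1, codons.BASE_INDEX[c[1]]]
            * freqs[2, codons.BASE_INDEX[c[2]]]
            for c in codons.SENSE_CODONS
        ]
    )
    return pi / pi.sum()


_FIT_BOUNDS = [
    (np.log(0.01), np.log(100.0)),   # log kappa
    (np.log(1e-4), np.log(10.0)),    # log omega_g
    (np.log(1e-6), np.log(100.0)),   # log rho
]


def fit_gene_model(
    aln: CodonAlignment,
    tree: Phylogeny,
    exclude_query: bool = True,
    min_taxa: int = 3,
    min_codons: int = 10,
    max_restarts: int = 2,
    seed: int = 0,
) -> CodonModelParams:
    """Maximum-likelihood (kappa, omega_g, rho) for one gene.

    Codon frequencies are F3x4 from the alignment; the query taxon is
    excluded from both the frequencies and the likelihood when masking is on.
    Optimization is bounded quasi-Newton (L-BFGS-B) on log parameters from a
    neutral-ish start, with seeded random restarts if convergence fails.
    """
    exclude = frozenset({aln.query_taxon}) if exclude_query else frozenset()
    rows = [
        i
        for i, t in enumerate(aln.taxa)
        if t not in exclude and np.any(aln.matrix[i] != codons.MISSING)
    ]
    if len(rows) < min_taxa:
        raise ValueError(
            f"need >= {min_taxa} informative taxa, have {len(rows)}"
        )
    if aln.n_codons < min_codons:
        raise ValueError(f"need >= {min_codons} codon columns, have {aln.n_codons}")

    pi = f3x4_frequencies(aln, exclude)
    columns = np.arange(aln.n_codons)

    def neg_loglik(x: np.ndarray) -> float:
        kappa, omega, rho = np.exp(x)
        params = CodonModelParams(kappa, omega, rho, pi)
        ws = LikelihoodWorkspace(aln, tree, params, exclude)
        return -float(ws.loglik(omega, columns).sum())

    rng = np.random.default_rng(seed)
    starts = [np.log([2.0, 0.5, 1.0])]
    for _ in range(max_restarts):
        starts.append(
            np.array(
                [rng.uniform(lo, hi) for lo, hi in _FIT_BOUNDS]
            )
        )
    best = None
    for attempt, x0 in enumerate(starts):
        res = optimize.minimize(
            neg_loglik,
            x0,
            method="L-BFGS-B",
            bounds=_FIT_BOUNDS,
            options={"maxiter": 200, "ftol": 1e-9, "eps": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            if attempt:
                logger.info("gene fit converged on restart %d", attempt)
            break
    if not best.success:
        # line searches on finite-difference gradients occasionally stall
        # near the optimum; a derivative-free polish settles it
        polish = optimize.minimize(
            neg_loglik,
            best.x,
            method="Nelder-Mead",
            bounds=_FIT_BOUNDS,
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
        )
        if polish.fun <= best.fun or polish.success:
            best = polish
    kappa, omega, rho = np.exp(best.x)
    params = CodonModelParams(
        kappa, omega, rho, pi, converged=bool(best.success), loglik=-best.fun
    )
    if not best.success:
        raise GeneFitError(
            f"gene-level fit did not converge: {best.message}", params=params
        )
    return params


# ---------------------------------------------------------------------------
# Site test and call rules
# ---------------------------------------------------------------------------

def _optimize_site_omega(
    ws: LikelihoodWorkspace,
    codon_index: int,
    log_bounds: tuple[float, float] | None = None,
):
    lo, hi = log_bounds or (np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1]))

    def neg(x: float) -> float:
        return -float(ws.loglik(np.exp(x), [codon_index])[0])

    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-5}
    )
    return float(np.exp(res.x)), -float(res.fun)


def test_site(
    aln: CodonAlignment,
    tree: Phylogeny,
    params: CodonModelParams,
    codon_index: int,
    min_species: int = DEFAULT_MIN_SPECIES,
    workspace: LikelihoodWorkspace | None = None,
    boundary_mixture: bool = False,
) -> SiteTestResult:
    """Constraint LRT at one codon with the query taxon masked.

    The null fixes the site omega at 1 (neutral); the alternative maximizes
    it over the configured bounds.  Codons with fewer than ``min_species``
    informative non-query species return verdict ``untested``.
    """
    if np.isnan(params.loglik) and not params.converged:
        raise ValueError("gene model parameters are not fitted")
    n_inf = aln.n_informative(codon_index, exclude_query=True)
    result = SiteTestResult(codon_index=codon_index, n_species_informative=n_inf)
    if n_inf < min_species:
        return result
    ws = workspace or LikelihoodWorkspace(
        aln, tree, params, frozenset({aln.query_taxon})
    )
    lnl0 = float(ws.loglik(1.0, [codon_index])[0])
    omega_hat, lnl1 = _optimize_site_omega(ws, codon_index)
    if lnl1 < lnl0:  # omega = 1 is in the alternative's parameter space
        omega_hat, lnl1 = 1.0, lnl0
    d = max(0.0, 2.0 * (lnl1 - lnl0))
    if boundary_mixture:
        p = 0.5 * float(stats.chi2.sf(d, df=1)) if d > 0 else 1.0
    else:
        p = float(stats.chi2.sf(d, df=1))
    result.lnl0 = lnl0
    result.lnl1 = lnl1
    result.omega_site = omega_hat
    result.statistic = d
    result.p_value = p
    result.verdict = "tolerated"
    return result


def allele_novelty(
    aln: CodonAlignment, column: int, ref_base: str, alt_base: str
) -> bool:
    """True iff ref or alt is unseen among non-query taxa at that column.

    With zero informative comparative states the flag is vacuously true
    (logged); such sites are normally already untested by the species rule.
    """
    states = aln.nucleotide_column(column)
    seen = {
        b
        for i, b in enumerate(states)
        if i != aln.query_index and b in "ACGT"
    }
    if not seen:
        logger.warning(
            "novelty check at column %d has no informative comparative states",
            column,
        )
        return True
    return ref_base.upper() not in seen or alt_base.upper() not in seen


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests for family-wise level alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def call_deleterious(result: SiteTestResult, threshold: float) -> str:
    """Apply the deleterious call rule; untested results pass through.

    Deleterious requires a Bonferroni-significant p-value, a constrained
    site (omega_hat < 1), and allele novelty relative to the other species.
    """
    if result.verdict == "untested":
        return "untested"
    if result.novel is None:
        raise ValueError("novelty flag not set on result")
    if result.p_value < threshold and result.novel and result.omega_site < 1.0:
        result.verdict = "deleterious"
    else:
        result.verdict = "tolerated"
    return result.verdict


class GeneLRT:
    """Convenience runner: fit a gene once, then test many codons cheaply."""

    def __init__(
        self,
        aln: CodonAlignment,
        tree: Phylogeny,
        params: CodonModelParams | None = None,
        min_species: int = DEFAULT_MIN_SPECIES,
        **fit_kwargs,
    ):
        self.aln = aln
        self.tree = tree
        self.min_species = min_species
        self.params = params if params is not None else fit_gene_model(
            aln, tree, **fit_kwargs
        )
        self.workspace = LikelihoodWorkspace(
            aln, tree, self.params, frozenset({aln.query_taxon})
        )

    def test(self, codon_index: int, **kwargs) -> SiteTestResult:
        return test_site(
            self.aln,
            self.tree,
            self.params,
            codon_index,
            min_species=self.min_species,
            workspace=self.workspace,
            **kwargs,
        )

    def test_all(
        self, columns=None, grid_size: int = 25, boundary_mixture: bool = False
    ) -> list[SiteTestResult]:
        """Test many codons, sharing work across sites.

        The null likelihood is computed in one vectorized pruning pass; the
        alternative uses a shared coarse grid over log-omega (vectorized per
        grid point) followed by per-site bounded refinement within the
        bracketing grid cells.  Identical to calling :meth:`test` per codon
        up to the optimizer tolerance.
        """
        if columns is None:
            columns = range(self.aln.n_codons)
        columns = np.asarray(list(columns), dtype=np.int64)
        n_inf = np.array(
            [self.aln.n_informative(c, exclude_query=True) for c in columns]
        )
        testable = n_inf >= self.min_species
        results = [
            SiteTestResult(codon_index=int(c), n_species_informative=int(k))
            for c, k in zip(columns, n_inf)
        ]
        if not testable.any():
            return results
        cols = columns[testable]
        ws = self.workspace
        lnl0 = ws.loglik(1.0, cols)
        log_grid = np.linspace(
            np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1]), grid_size
        )
        grid_lnl = np.stack([ws.loglik(np.exp(g), cols) for g in log_grid])
        best = np.argmax(grid_lnl, axis=0)
        for j, (col, res_idx) in enumerate(
            zip(cols, np.nonzero(testable)[0])
        ):
            k = best[j]
            lo = log_grid[max(k - 1, 0)]
            hi = log_grid[min(k + 1, grid_size - 1)]
            omega_hat, lnl1 = _optimize_site_omega(ws, int(col), (lo, hi))
            l0 = float(lnl0[j])
            if lnl1 < l0:
                omega_hat, lnl1 = 1.0, l0
            d = max(0.0, 2.0 * (lnl1 - l0))
            if boundary_mixture:
                p = 0.5 * float(stats.chi2.sf(d, df=1)) if d > 0 else 1.0
            else:
                p = float(stats.chi2.sf(d, df=1))
            r = results[res_idx]
            r.lnl0, r.lnl1, r.omega_site = l0, lnl1, omega_hat
            r.statistic, r.p_value, r.verdict = d, p, "tolerated"
        return results
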