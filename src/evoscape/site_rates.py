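"""Per-site evolutionary rate estimation by empirical Bayes on a fixed tree.

The model is the standard one behind Rate4Site-style analyses: sites evolve
independently under a reversible amino-acid replacement process (JTT by
default) whose rate at each site is a multiplier drawn from a discrete-gamma
prior with K equal-probability categories. For each alignment column c the
likelihood L_c(r_k) is computed by Felsenstein pruning at each category rate
r_k; the reported site rate is the posterior mean

    r_hat_c = sum_k r_k L_c(r_k) / sum_k L_c(r_k)

and rates are standardized to Z scores (mean 0, population SD 1) across the
columns that carry data. Gaps and 'X' are missing data: their leaf partial
vectors are all-ones. Branch lengths are taken from the input tree and never
re-optimized. The gamma shape alpha is either supplied or estimated by
maximizing the marginal log-likelihood over a bracketed scalar search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._jtt import AA_ORDER, JTT_FREQS, jtt_exchangeabilities
from .formats_io import ColumnMap, ConsistencyError, MultipleAlignment, PhyloTree

__all__ = [
    "SubstitutionModel",
    "GammaCategories",
    "SiteRateResult",
    "jtt_model",
    "column_likelihood",
    "site_log_likelihoods",
    "estimate_alpha",
    "posterior_mean_rates",
    "standardize_z",
    "project_rates",
    "write_rates",
]

ALPHA_BOUNDS = (0.02, 20.0)


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionModel:
    """Reversible amino-acid replacement model Q = S diag(pi), normalized so
    the expected substitution rate at stationarity is 1.

    The symmetric exchangeability matrix S and stationary frequencies pi
    determine Q; transition matrices P(t) = expm(Q t) are computed through the
    eigendecomposition of the symmetrized form diag(sqrt pi) Q diag(1/sqrt pi),
    done once at construction.
    """

    S: np.ndarray
    pi: np.ndarray
    name: str = "custom"
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(init=False, repr=False)
    Q: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("S must be a symmetric 20x20 matrix")
        if pi.shape != (20,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be positive and sum to 1")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))  # expected rate at stationarity
        Q /= mu
        self.Q = Q
        sqrt_pi = np.sqrt(pi)
        B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        B = 0.5 * (B + B.T)  # symmetrize away rounding noise
        w, U = np.linalg.eigh(B)
        left = U / sqrt_pi[:, None]      # diag(1/sqrt pi) U
        right = (U * sqrt_pi[:, None]).T  # U^T diag(sqrt pi)
        self.pi = pi
        self.S = S
        self._eig = (w, left, right)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); exact identity at t = 0."""
        if t < 0:
            raise ValueError("branch length x rate must be non-negative")
        if t == 0.0:
            return np.eye(20)
        w, left, right = self._eig
        P = (left * np.exp(w * t)) @ right
        np.clip(P, 0.0, None, out=P)
        return P

    def aa_index(self, ch: str) -> int | None:
        """Index of an amino acid in model order; None for gap/'X'."""
        i = AA_ORDER.find(ch)
        return i if i >= 0 else None


def jtt_model(aln: MultipleAlignment | None = None, plus_f: bool = False
              ) -> SubstitutionModel:
    """The JTT model; with ``plus_f`` the stationary frequencies are replaced
    by the observed alignment frequencies (the "+F" variant)."""
    if plus_f:
        if aln is None:
            raise ValueError("plus_f requires an alignment")
        pi = np.empty(20)
        from .formats_io import AMINO_ACIDS
        freqs = aln.observed_frequencies()
        for i, a in enumerate(AA_ORDER):
            pi[i] = freqs[AMINO_ACIDS.index(a)]
        return SubstitutionModel(jtt_exchangeabilities(), pi, name="jtt+f")
    return SubstitutionModel(jtt_exchangeabilities(), JTT_FREQS.copy(), name="jtt")


# ---------------------------------------------------------------------------
# Discrete-gamma rate categories
# ---------------------------------------------------------------------------

@dataclass
class GammaCategories:
    """K equal-probability discrete-gamma rate categories (mean-of-bin rates).

    The prior is Gamma(shape=alpha, rate=alpha), so the continuous mean is 1;
    using the conditional mean within each equal-probability bin keeps the
    mean of the category rates exactly 1.
    """

    alpha: float
    K: int
    rates: np.ndarray

    @classmethod
    def discretize(cls, alpha: float, K: int = 16) -> "GammaCategories":
        if alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if K < 1:
            raise ValueError("need at least one category")
        qs = np.arange(1, K) / K
        cuts = special.gammaincinv(alpha, qs) / alpha  # quantile boundaries
        upper = np.concatenate([alpha * cuts, [np.inf]])
        lower = np.concatenate([[0.0], alpha * cuts])
        mass_hi = special.gammainc(alpha + 1, upper)
        mass_lo = special.gammainc(alpha + 1, lower)
        rates = K * (mass_hi - mass_lo)
        return cls(alpha=alpha, K=K, rates=rates)

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.K, 1.0 / self.K)


# ---------------------------------------------------------------------------
# Pruning likelihoods
# ---------------------------------------------------------------------------

def _leaf_partials(aln: MultipleAlignment, tree: PhyloTree,
                   model: SubstitutionModel) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Per-leaf (L, 20) partial likelihood matrices, plus a no-data mask.

    Gap and 'X' characters get all-ones vectors (missing data); the no-data
    mask marks columns where *every* taxon is gap/'X'.
    """
    if set(tree.leaf_labels) != set(aln.taxa):
        raise ConsistencyError("tree leaves and alignment taxa differ")
    L = aln.length
    partials: dict[int, np.ndarray] = {}
    any_data = np.zeros(L, dtype=bool)
    for node in tree.leaves:
        row = aln.row(tree.labels[node])
        M = np.ones((L, 20))
        for c, ch in enumerate(row):
            i = model.aa_index(ch)
            if i is not None:
                M[c] = 0.0
                M[c, i] = 1.0
                any_data[c] = True
        partials[node] = M
    return partials, ~any_data


def _prune_one_rate(tree: PhyloTree, model: SubstitutionModel, rate: float,
                    leaf_partials: dict[int, np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Linear-space pruning with per-column rescaling.

    Returns (likelihood, logscale): the column likelihood is
    ``likelihood * exp(logscale)``. Columns with zero likelihood keep
    likelihood 0 (log -inf downstream).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    L = next(iter(leaf_partials.values())).shape[0]
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(L)
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            partial[node] = leaf_partials[node]
            continue
        M = np.ones((L, 20))
        for k in kids:
            P = model.transition_matrix(tree.lengths[k] * rate)
            M *= partial.pop(k) @ P.T
        scale = M.max(axis=1)
        nz = scale > 0
        safe = np.where(nz, scale, 1.0)
        M /= safe[:, None]
        logscale += np.where(nz, np.log(safe), 0.0)
        partial[node] = M
    root = partial[tree.root]
    like = root @ model.pi
    return like, logscale


def column_likelihood(aln: MultipleAlignment, tree: PhyloTree,
                      model: SubstitutionModel, rate: float, column: int) -> float:
    """Likelihood of one alignment column (1-based) at a given rate multiplier.

    Exact in the zero-rate limit: a constant column at residue a has
    likelihood pi_a and any variable column has likelihood 0.
    """
    if not (1 <= column <= aln.length):
        raise ValueError(f"column {column} outside 1..{aln.length}")
    partials, _ = _leaf_partials(aln, tree, model)
    sub = {n: M[[column - 1]] for n, M in partials.items()}
    like, logscale = _prune_one_rate(tree, model, rate, sub)
    return float(like[0] * np.exp(logscale[0]))


def site_log_likelihoods(aln: MultipleAlignment, tree: PhyloTree,
                         model: SubstitutionModel, rates: np.ndarray,
                         _partials: tuple | None = None) -> np.ndarray:
    """(n_rates, L) per-column log-likelihoods at each rate multiplier."""
    partials, _ = _partials if _partials is not None else _leaf_partials(aln, tree, model)
    out = np.empty((len(rates), aln.length))
    with np.errstate(divide="ignore"):
        for i, r in enumerate(rates):
            like, logscale = _prune_one_rate(tree, model, float(r), partials)
            out[i] = np.log(like) + logscale
    return out


# ---------------------------------------------------------------------------
# Alpha estimation and posterior rates
# ---------------------------------------------------------------------------

def _marginal_loglike(loglikes: np.ndarray, K: int) -> float:
    """sum_c log[(1/K) sum_k L_c(r_k)]."""
    return float(np.sum(special.logsumexp(loglikes, axis=0) - np.log(K)))


def estimate_alpha(aln: MultipleAlignment, tree: PhyloTree,
                   model: SubstitutionModel, K: int = 16) -> float:
    """Maximum-likelihood gamma shape over a bounded search in [0.02, 20].

    Deterministic given its inputs. If the optimum sits at a search boundary
    (e.g. a single invariant column carries no rate signal) the boundary value
    is returned with a warning.
    """
    cache = _leaf_partials(aln, tree, model)
    if cache[1].all():
        raise ValueError("cannot estimate alpha: every column is gap/'X' only")

    def neg_loglike(alpha: float) -> float:
        gamma = GammaCategories.discretize(alpha, K)
        ll = site_log_likelihoods(aln, tree, model, gamma.rates, _partials=cache)
        return -_marginal_loglike(ll, K)

    res = optimize.minimize_scalar(
        neg_loglike, bounds=ALPHA_BOUNDS, method="bounded",
        options={"xatol": 1e-4})
    candidates = [ALPHA_BOUNDS[0], float(res.x), ALPHA_BOUNDS[1]]
    values = [neg_loglike(a) for a in candidates]
    best = int(np.argmin(values))
    alpha = candidates[best]
    if best != 1:
        warnings.warn(
            f"gamma shape pinned to search boundary alpha={alpha}; the "
            "alignment carries little or no among-site rate signal",
            stacklevel=2)
    return alpha


@dataclass
class SiteRateResult:
    """Posterior-mean site rates with Z standardization, alignment coordinates.

    ``no_data`` flags columns where every taxon is gap/'X'; those columns are
    assigned the prior mean rate and carry no Z score (NaN).
    """

    rates: np.ndarray
    z: np.ndarray
    no_data: np.ndarray
    alpha: float
    K: int
    log_likelihood: float


def posterior_mean_rates(aln: MultipleAlignment, tree: PhyloTree,
                         model: SubstitutionModel, gamma: GammaCategories
                         ) -> SiteRateResult:
    """Empirical-Bayes posterior mean rate per alignment column."""
    cache = _leaf_partials(aln, tree, model)
    no_data = cache[1].copy()
    loglikes = site_log_likelihoods(aln, tree, model, gamma.rates, _partials=cache)
    log_norm = special.logsumexp(loglikes, axis=0)
    with np.errstate(invalid="ignore"):
        w = np.exp(loglikes - log_norm[None, :])
    rates = gamma.rates @ w
    prior_mean = float(gamma.rates.mean())
    rates[no_data] = prior_mean
    if np.any(~np.isfinite(rates)):
        raise ArithmeticError("non-finite posterior rate encountered")
    z = standardize_z(rates, no_data)
    total = _marginal_loglike(loglikes[:, ~no_data], gamma.K)
    return SiteRateResult(rates=rates, z=z, no_data=no_data,
                          alpha=gamma.alpha, K=gamma.K, log_likelihood=total)


def standardize_z(rates: np.ndarray, flags: np.ndarray | None = None) -> np.ndarray:
    """Standardize to mean 0, population SD 1 over non-flagged entries.

    Flagged entries come back as NaN. A constant (zero-spread) input is
    degenerate and raises.
    """
    rates = np.asarray(rates, dtype=float)
    if flags is None:
        flags = np.zeros(len(rates), dtype=bool)
    vals = rates[~flags]
    if len(vals) < 2:
        raise ValueError("need at least two data columns to standardize")
    sd = vals.std()  # population SD (ddof=0)
    if sd == 0:
        raise ValueError("zero spread: rates are constant, Z undefined")
    z = np.full(len(rates), np.nan)
    z[~flags] = (vals - vals.mean()) / sd
    return z


def project_rates(result: SiteRateResult, column_map: ColumnMap) -> pd.DataFrame:
    """Per-reference-residue table (pos, rate, z, no_data); reference-gap
    columns are dropped."""
    rows = []
    for col, res in enumerate(column_map.column_to_residue, start=1):
        if res is None:
            continue
        rows.append((res, result.rates[col - 1], result.z[col - 1],
                     bool(result.no_data[col - 1])))
    return pd.DataFrame(rows, columns=["pos", "rate", "z", "no_data"])


def write_rates(table: pd.DataFrame, path, *, model: str, K: int, alpha: float) -> None:
    from .formats_io import _comment_header

    with open(path, "w") as fh:
        fh.write(_comment_header(model=model, K=K, alpha=f"{alpha:.6g}",
                                 coords="1-based") + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
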