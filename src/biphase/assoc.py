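"""Recessive and additive association testing with saddlepoint correction.

The workhorse is a covariate-adjusted logistic score test: the null model
is fitted on covariates only, the score for a genotype vector ``g`` is
``T = g' (y - mu)`` and its variance is the efficient information after
projecting ``g`` off the covariate space.  For unbalanced case-control
ratios the normal approximation to the score distribution is poor in the
tails, so tail probabilities are corrected with a saddlepoint approximation
to the cumulant generating function of the adjusted score (engaged when the
standardized score exceeds 2 in magnitude; below that the normal
approximation is used).

Samples are assumed unrelated, so no genetic relatedness matrix enters the
null model.  Conditioning (polygenic-score covariate, iteratively selected
nearby common variants, rare and collapsed ultra-rare burden, additive
dosage) is absorbed into the null model covariates, with provenance
recorded on each result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm


@dataclass
class AssocConfig:
    """Scan thresholds and sample-size bookkeeping."""

    alpha: float = 0.05
    min_biallelic_carriers: int = 5
    min_disrupted_haplotypes: int = 10
    region_window: int = 1_000_000
    conditional_p_stop: float = 5e-6
    max_conditional_signals: int = 25
    spa_z_threshold: float = 2.0

    def __post_init__(self) -> None:
        if min(
            self.alpha,
            self.min_biallelic_carriers,
            self.min_disrupted_haplotypes,
            self.conditional_p_stop,
        ) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class NullModel:
    """Covariate-only logistic fit: fitted case probabilities and projections."""

    X: np.ndarray
    y: np.ndarray
    mu: np.ndarray
    converged: bool

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.mu

    @property
    def weights(self) -> np.ndarray:
        return self.mu * (1.0 - self.mu)


def fit_null_model(
    phenotype: np.ndarray, covariates: np.ndarray | None = None
) -> NullModel:
    """Fit the covariate-only logistic null model (intercept always included)."""
    y = np.asarray(phenotype, dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("phenotype must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one case and one control")
    n = y.size
    if covariates is None or np.size(covariates) == 0:
        X = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([np.ones(n), C])
        # drop columns that do not add rank (constant or collinear covariates)
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                warnings.warn(f"dropping collinear covariate column {j - 1}")
        X = X[:, keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            converged = bool(res.converged)
            mu = np.asarray(res.mu)
        except Exception:
            converged = False
            mu = np.full(n, y.mean())
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    return NullModel(X=X, y=y, mu=mu, converged=converged)


@dataclass
class ScoreTest:
    """Score statistic, its variance and the (possibly SPA-corrected) p."""

    score: float
    variance: float
    z: float
    p_normal: float
    p: float
    spa_used: bool
    spa_converged: bool


def _adjusted_genotype(g: np.ndarray, null: NullModel) -> np.ndarray:
    """Project g off the covariate space under the null weights."""
    W = null.weights
    X = null.X
    XtWX = X.T @ (W[:, None] * X)
    beta = np.linalg.solve(XtWX, X.T @ (W * g))
    return g - X @ beta


def score_test_components(
    G: np.ndarray, null: NullModel
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and efficient variances for one or more genotype columns."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != null.y.size:
        G = G.T
    W = null.weights
    X = null.X
    T = G.T @ null.residuals
    q = X.T @ (W[:, None] * G)
    XtWX = X.T @ (W[:, None] * X)
    sol = np.linalg.solve(XtWX, q)
    V = (W[:, None] * G * G).sum(axis=0) - np.einsum("pk,pk->k", q, sol)
    return T, np.maximum(V, 0.0)


def _lattice_spacing(genotype: np.ndarray) -> float | None:
    """Spacing of the genotype lattice, or None when not a regular lattice."""
    vals = np.unique(genotype)
    if vals.size < 2 or vals.size > 3:
        return None
    gaps = np.diff(vals)
    if np.allclose(gaps, gaps[0]):
        return float(gaps[0])
    return None


def _conditional_spa_tail(
    s: float, g_adj: np.ndarray, mu: np.ndarray, h: float | None
) -> tuple[float, bool]:
    """One tail of the score conditional on the case total (Skovgaard).

    Approximates ``P(S1 >= s | S2 = 0)`` (upper for s > 0, lower for
    s < 0) where ``S1 = sum g~_i (y_i - mu_i)`` and ``S2 = sum (y_i -
    mu_i)``, by a damped-Newton solve of the two-dimensional saddlepoint
    equations and the Barndorff-Nielsen formula with Skovgaard's
    denominator; when ``h`` is given, Daniels' lattice correction replaces
    the Gaussian ``u`` term (the conditional score lives on a lattice of
    spacing ``h`` for collapsed genotypes).
    """
    g = np.asarray(g_adj, dtype=float)
    mu = np.asarray(mu, dtype=float)
    gm = g @ mu
    m1 = mu.sum()
    K22_0 = (mu * (1 - mu)).sum()
    var = float((g * g * mu * (1 - mu)).sum())
    if var <= 0 or K22_0 <= 0:
        return np.nan, False
    if abs(s) / np.sqrt(var) < 1e-4:
        return 0.5, True

    def K(l1, l2):
        return float(
            np.log1p(mu * np.expm1(np.clip(g * l1 + l2, -700, 700))).sum()
            - l1 * gm - l2 * m1
        )

    def grad_hess(l1, l2):
        eta = np.clip(g * l1 + l2, -700, 700)
        e = np.exp(eta)
        p = mu * e / (1 - mu + mu * e)
        gr = np.array([(p * g).sum() - gm, p.sum() - m1])
        v = p * (1 - p)
        H = np.array([[(v * g * g).sum(), (v * g).sum()], [(v * g).sum(), v.sum()]])
        return gr, H

    target = np.array([s, 0.0])
    lam = np.zeros(2)
    gr, H = grad_hess(*lam)
    r = gr - target
    for _ in range(400):
        if np.max(np.abs(r)) < 1e-10 * max(1.0, abs(s)):
            break
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(2), r)
        except np.linalg.LinAlgError:
            return np.nan, False
        t = 1.0
        while t > 1e-14:
            nl = lam - t * step
            gr2, H2 = grad_hess(*nl)
            r2 = gr2 - target
            if np.all(np.isfinite(r2)) and np.linalg.norm(r2) < np.linalg.norm(r):
                lam, gr, H, r = nl, gr2, H2, r2
                break
            t *= 0.5
        else:
            break
    if np.max(np.abs(r)) > 1e-5 * max(1.0, abs(s)):
        return np.nan, False
    arg = float(lam @ target - K(*lam))
    detH = float(np.linalg.det(H))
    if arg <= 0 or detH <= 0:
        return np.nan, False
    w = np.sign(lam[0]) * np.sqrt(2 * arg)
    if h is not None and lam[0] != 0.0:
        u = (1.0 - np.exp(-lam[0] * h)) * np.sqrt(detH / K22_0) / h
    else:
        u = lam[0] * np.sqrt(detH / K22_0)
    if abs(w) < 1e-6 or u <= 0 and s > 0 or u >= 0 and s < 0:
        # near the center or sign-inconsistent root: not a usable tail
        if abs(w) < 1e-6:
            return float(stats.norm.sf(abs(s) / np.sqrt(var))), True
        return np.nan, False
    z_star = w + np.log(abs(u) / abs(w)) / w
    tail = stats.norm.sf(z_star) if s > 0 else stats.norm.cdf(z_star)
    return float(tail), True


def _unconditional_spa_tail(
    s: float, g_adj: np.ndarray, mu: np.ndarray
) -> tuple[float, bool]:
    """One tail of the unconditional adjusted score (single saddlepoint)."""
    g = np.asarray(g_adj, dtype=float)
    mu = np.asarray(mu, dtype=float)
    nz = g != 0.0
    g, mu = g[nz], mu[nz]
    gm = float(g @ mu)
    var = float((g * g * mu * (1 - mu)).sum())
    if var <= 0:
        return np.nan, False
    if abs(s) / np.sqrt(var) < 1e-4:
        return 0.5, True

    def K(t):
        return np.log1p(mu * np.expm1(np.clip(g * t, -700, 700))).sum() - t * gm

    def K1(t):
        e = np.exp(np.clip(g * t, -700, 700))
        return float((mu * g * e / (1 - mu + mu * e)).sum()) - gm

    def K2(t):
        e = np.exp(np.clip(g * t, -700, 700))
        d = 1 - mu + mu * e
        return float((g * g * mu * (1 - mu) * e / (d * d)).sum())

    lo, hi = (0.0, 1.0) if s > 0 else (-1.0, 0.0)
    for _ in range(100):
        if (K1(hi) - s) * (K1(lo) - s) <= 0:
            break
        lo = lo * 2 if s < 0 else lo
        hi = hi * 2 if s > 0 else hi
        if max(abs(lo), abs(hi)) > 1e8:
            return np.nan, False
    try:
        t_hat = optimize.brentq(lambda t: K1(t) - s, lo, hi, xtol=1e-12)
    except ValueError:
        return np.nan, False
    k2 = K2(t_hat)
    arg = t_hat * s - K(t_hat)
    if k2 <= 0 or arg <= 0:
        return np.nan, False
    w = np.sign(t_hat) * np.sqrt(2 * arg)
    v = t_hat * np.sqrt(k2)
    if abs(w) < 1e-6 or abs(v) < 1e-12:
        return float(stats.norm.sf(abs(s) / np.sqrt(var))), True
    z_star = w + np.log(v / w) / w
    tail = stats.norm.sf(z_star) if s > 0 else stats.norm.cdf(z_star)
    return float(tail), True


def _exact_conditional_count_tail(
    genotype: np.ndarray,
    y: np.ndarray,
    mu: np.ndarray,
    k_threshold: float,
    upper: bool,
) -> tuple[float, bool]:
    """Exact conditional carrier-count tail for a two-valued genotype.

    Conditional on the case total, the number of case carriers follows
    Fisher's noncentral hypergeometric distribution with the mean carrier
    vs non-carrier odds; without covariates the odds are 1 and this is
    exactly the Fisher tail.  Used where the conditional saddlepoint
    diverges (score threshold at or beyond the conditional support edge).
    """
    from scipy.special import gammaln, logsumexp

    carrier = genotype > genotype.min()
    c = int(carrier.sum())
    n = genotype.size
    T = int(round(float(y.sum())))
    odds = mu / (1 - mu)
    psi = float(odds[carrier].mean() / odds[~carrier].mean())
    k_min = max(0, T - (n - c))
    k_max = min(c, T)
    ks = np.arange(k_min, k_max + 1)
    # log pmf up to normalization: C(c,k) C(n-c,T-k) psi^k
    logw = (
        gammaln(c + 1) - gammaln(ks + 1) - gammaln(c - ks + 1)
        + gammaln(n - c + 1) - gammaln(T - ks + 1) - gammaln(n - c - T + ks + 1)
        + ks * np.log(psi)
    )
    logw -= logsumexp(logw)
    if upper:
        k = int(np.ceil(k_threshold - 1e-6))
        if k > k_max:
            return 0.0, True
        return float(np.exp(logsumexp(logw[ks >= k]))), True
    k = int(np.floor(k_threshold + 1e-6))
    if k < k_min:
        return 0.0, True
    return float(np.exp(logsumexp(logw[ks <= k]))), True


def saddlepoint_pvalue(
    score: float,
    genotype: np.ndarray,
    null: "NullModel",
    g_adjusted: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Two-sided saddlepoint-corrected tail probability of the score.

    Each tail of the covariate-adjusted score is approximated by a double
    saddlepoint conditional on the case total (the margin whose neglect
    makes the normal approximation fail under extreme imbalance), with a
    lattice correction for collapsed 0/2 and 0/1/2 genotypes.  Where the
    saddlepoint equations cannot be solved — the observed score at the
    boundary of the conditional support, e.g. every carrier a case — the
    tail is the exact conditional carrier-count tail for two-valued
    genotypes, the unconditional saddlepoint otherwise.  Returns
    ``(p, converged)``; a non-convergent result reverts to the normal
    approximation upstream.
    """
    g = np.asarray(genotype, dtype=float)
    mu = null.mu
    if g_adjusted is None:
        g_adjusted = _adjusted_genotype(g, null)
    h = _lattice_spacing(g)
    vals = np.unique(g)
    two_valued = vals.size == 2
    var = float((g_adjusted**2 * mu * (1 - mu)).sum())
    if var <= 0:
        return 1.0, True
    t_obs = float(score)
    if two_valued:
        carrier = g > vals[0]
        k_obs = int((carrier & (null.y == 1)).sum())
        slope = float(vals[1] - vals[0])  # score change per case carrier
        c = int(carrier.sum())
        T = int(round(float(null.y.sum())))
        k_min = max(0, T - (g.size - c))
        k_max = min(c, T)

    def tail(s: float) -> tuple[float, bool]:
        if two_valued:
            # map the score threshold to a carrier-count threshold; at or
            # beyond the conditional support edge the saddlepoint diverges,
            # so use the exact conditional count tail there directly
            k_t = k_obs + (s - t_obs) / slope
            at_edge = (s > 0 and k_t >= k_max - 0.5) or (s < 0 and k_t <= k_min + 0.5)
            if at_edge:
                return _exact_conditional_count_tail(g, null.y, mu, k_t, upper=s > 0)
        p, ok = _conditional_spa_tail(s, g_adjusted, mu, h)
        if ok:
            return p, True
        if two_valued:
            return _exact_conditional_count_tail(g, null.y, mu, k_t, upper=s > 0)
        return _unconditional_spa_tail(s, g_adjusted, mu)

    s = abs(float(score))
    up, ok_up = tail(s)
    lo, ok_lo = tail(-s)
    if not (ok_up and ok_lo):
        p = float(2 * stats.norm.sf(s / np.sqrt(var)))
        return min(p, 1.0), False
    return float(min(up + lo, 1.0)), True


def logistic_score_test(
    genotype: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    null: NullModel | None = None,
    spa_z_threshold: float = 2.0,
) -> ScoreTest:
    """Covariate-adjusted logistic score test with saddlepoint tails.

    ``null`` may be supplied to reuse one covariate-only fit across many
    genotype vectors.  Raises on monomorphic genotypes.
    """
    g = np.asarray(genotype, dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("monomorphic genotype")
    if null is None:
        null = fit_null_model(phenotype, covariates)
    T, V = score_test_components(g[:, None], null)
    T, V = float(T[0]), float(V[0])
    if V <= 0:
        return ScoreTest(T, V, 0.0, 1.0, 1.0, False, True)
    z = T / np.sqrt(V)
    p_normal = float(2 * stats.norm.sf(abs(z)))
    spa_used = abs(z) > spa_z_threshold
    p, spa_ok = (p_normal, True)
    if spa_used:
        p, spa_ok = saddlepoint_pvalue(T, g, null)
        if not spa_ok:
            p = p_normal
    return ScoreTest(T, V, float(z), p_normal, p, spa_used, spa_ok)


# ---------------------------------------------------------------------------
# scans


@dataclass
class AssociationResult:
    gene: str
    trait: str
    model: str
    score: float
    variance: float
    p_value: float
    direction: int
    n_biallelic_cases: int
    n_biallelic_controls: int
    n_monoallelic: int
    conditioning: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        import dataclasses

        d = dataclasses.asdict(self)
        d["conditioning"] = ";".join(self.conditioning) or "none"
        return d


def _scan(
    matrix: np.ndarray,
    genes: np.ndarray,
    phenotypes: pd.DataFrame,
    traits: list[str],
    covariate_cols: list[str],
    config: AssocConfig,
    model: str,
    prs_cols: dict[str, str] | None = None,
) -> pd.DataFrame:
    prs_cols = prs_cols or {}
    results = []
    for trait in traits:
        y_all = phenotypes[trait]
        keep = y_all.notna().to_numpy()
        y = y_all.to_numpy(dtype=float)[keep]
        if y.sum() == 0 or y.sum() == y.size:
            continue
        cov_names = list(covariate_cols)
        conditioning = []
        if trait in prs_cols:
            cov_names.append(prs_cols[trait])
            conditioning.append(f"prs:{prs_cols[trait]}")
        C = phenotypes.loc[keep, cov_names].to_numpy(dtype=float) if cov_names else None
        null = fit_null_model(y, C)
        G = matrix[keep]
        if model == "recessive":
            eligible = (G == 2).sum(axis=0) >= config.min_biallelic_carriers
        else:
            eligible = G.sum(axis=0) >= config.min_disrupted_haplotypes
        eligible &= np.ptp(G, axis=0) > 0
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            continue
        T, V = score_test_components(G[:, idx].astype(float), null)
        z = np.divide(T, np.sqrt(V), out=np.zeros_like(T), where=V > 0)
        for k, j in enumerate(idx):
            if V[k] <= 0:
                continue
            p_normal = float(2 * stats.norm.sf(abs(z[k])))
            p = p_normal
            if abs(z[k]) > config.spa_z_threshold:
                p, ok = saddlepoint_pvalue(float(T[k]), G[:, j].astype(float), null)
                if not ok:
                    p = p_normal
            carrier = G[:, j] == 2
            results.append(
                AssociationResult(
                    gene=str(genes[j]),
                    trait=trait,
                    model=model,
                    score=float(T[k]),
                    variance=float(V[k]),
                    p_value=p,
                    direction=int(np.sign(T[k])) if T[k] else 0,
                    n_biallelic_cases=int((carrier & (y == 1)).sum()),
                    n_biallelic_controls=int((carrier & (y == 0)).sum()),
                    n_monoallelic=int((G[:, j] == 1).sum()),
                    conditioning=tuple(conditioning),
                ).to_dict()
            )
    out = pd.DataFrame(
        results,
        columns=[
            "gene",
            "trait",
            "model",
            "score",
            "variance",
            "p_value",
            "direction",
            "n_biallelic_cases",
            "n_biallelic_controls",
            "n_monoallelic",
            "conditioning",
        ],
    )
    if not out.empty:
        n_genes = out["gene"].nunique()
        n_traits = out["trait"].nunique()
        out.attrs["bonferroni"] = bonferroni_threshold(config.alpha, n_genes, n_traits)
    return out


def run_recessive_scan(
    encodings,
    phenotypes: pd.DataFrame,
    traits: list[str],
    covariate_cols: list[str] | None = None,
    config: AssocConfig | None = None,
    prs_cols: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Recessive (0/2) gene-trait scan.

    Tests only (gene, trait) pairs with at least
    ``config.min_biallelic_carriers`` bi-allelic carriers among samples
    with non-missing phenotype; attaches the Bonferroni threshold for the
    tested grid as ``DataFrame.attrs['bonferroni']``.  ``prs_cols`` maps a
    trait to the phenotype-table column holding its off-chromosome
    polygenic score, appended to the covariates for that trait.
    """
    config = config or AssocConfig()
    return _scan(
        np.asarray(encodings.recessive),
        encodings.genes,
        phenotypes,
        traits,
        covariate_cols or [],
        config,
        "recessive",
        prs_cols,
    )


def run_additive_scan(
    encodings,
    phenotypes: pd.DataFrame,
    traits: list[str],
    covariate_cols: list[str] | None = None,
    config: AssocConfig | None = None,
    prs_cols: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Additive (0/1/2 affected gene copies) scan.

    Requires at least ``config.min_disrupted_haplotypes`` disrupted
    haplotypes (sum of the additive vector) per gene.
    """
    config = config or AssocConfig()
    return _scan(
        np.asarray(encodings.additive),
        encodings.genes,
        phenotypes,
        traits,
        covariate_cols or [],
        config,
        "additive",
        prs_cols,
    )


def iterative_conditional_scan(
    region_dosages: np.ndarray,
    positions: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    config: AssocConfig | None = None,
) -> list[int]:
    """Greedy forward selection of independent common-variant signals.

    Repeatedly tests every remaining variant in the region conditional on
    the signals selected so far, adds the most significant one, and stops
    when the best conditional p-value is not below
    ``config.conditional_p_stop`` or ``config.max_conditional_signals``
    signals are selected.  Ties break by larger absolute score, then lower
    genomic position.  Returns column indices into ``region_dosages``.
    """
    config = config or AssocConfig()
    D = np.atleast_2d(np.asarray(region_dosages, dtype=float))
    if D.size == 0:
        return []
    positions = np.asarray(positions)
    y = np.asarray(phenotype, dtype=float)
    base = (
        np.empty((y.size, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if base.shape[0] != y.size:
        base = base.T
    selected: list[int] = []
    remaining = [j for j in range(D.shape[1]) if np.ptp(D[:, j]) > 0]
    while remaining and len(selected) < config.max_conditional_signals:
        C = np.column_stack([base] + [D[:, [j]] for j in selected]) if (
            base.size or selected
        ) else None
        null = fit_null_model(y, C)
        T, V = score_test_components(D[:, remaining], null)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(T) / np.sqrt(V)
        z = np.nan_to_num(z)
        p = 2 * stats.norm.sf(z)
        order = sorted(
            range(len(remaining)),
            key=lambda k: (p[k], -abs(T[k]), positions[remaining[k]]),
        )
        best = order[0]
        if p[best] >= config.conditional_p_stop:
            break
        selected.append(remaining[best])
        remaining.pop(best)
    return selected


def conditional_test(
    genotype: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    conditioning: dict[str, np.ndarray],
    config: AssocConfig | None = None,
) -> tuple[ScoreTest, tuple[str, ...]]:
    """Score test with conditioning columns absorbed into the null model.

    ``conditioning`` maps a provenance label (e.g. ``"prs"``,
    ``"common:chr1:123"``, ``"ultra_rare_burden"``, ``"additive_dosage"``)
    to a per-sample column.  Columns collinear with the existing design are
    dropped with a warning.  Returns the test and the provenance tuple of
    columns actually absorbed.
    """
    config = config or AssocConfig()
    y = np.asarray(phenotype, dtype=float)
    base = (
        np.ones((y.size, 1))
        if covariates is None
        else np.column_stack([np.ones(y.size), np.atleast_2d(np.asarray(covariates, float))])
    )
    if base.shape[0] != y.size:
        base = base.T
    design = base
    used = []
    for label, col in conditioning.items():
        col = np.asarray(col, dtype=float).reshape(-1, 1)
        trial = np.column_stack([design, col])
        if np.linalg.matrix_rank(trial) > np.linalg.matrix_rank(design):
            design = trial
            used.append(label)
        else:
            warnings.warn(f"dropping collinear conditioning column {label!r}")
    cov = design[:, 1:] if design.shape[1] > 1 else None
    null = fit_null_model(y, cov)
    g = np.asarray(genotype, dtype=float)
    T, V = score_test_components(g[:, None], null)
    T, V = float(T[0]), float(V[0])
    if V <= 1e-12:
        return ScoreTest(T, V, 0.0, 1.0, 1.0, False, True), tuple(used)
    z = T / np.sqrt(V)
    p_normal = float(2 * stats.norm.sf(abs(z)))
    p, spa_used, ok = p_normal, False, True
    if abs(z) > config.spa_z_threshold:
        spa_used = True
        p, ok = saddlepoint_pvalue(T, g, null)
        if not ok:
            p = p_normal
    return ScoreTest(T, V, float(z), p_normal, p, spa_used, ok), tuple(used)


# ---------------------------------------------------------------------------
# analytic utilities


def bonferroni_threshold(alpha: float, n_genes: int, n_traits: int) -> float:
    """Family-wise threshold ``alpha / (n_genes * n_traits)``."""
    if n_genes <= 0 or n_traits <= 0:
        raise ValueError("gene and trait counts must be positive")
    return alpha / (n_genes * n_traits)


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Balanced-design equivalent ``n_eff = 4 / (1/n_cases + 1/n_controls)``."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def one_sided_sign_test(k_successes: int, n_pairs: int) -> float:
    """Upper-tail binomial sign test ``P(X >= k | n, 1/2)``."""
    if not 0 <= k_successes <= n_pairs:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k_successes - 1, n_pairs, 0.5))


def prs_maf_filter(
    n_cases: float,
    n_controls: float,
    floor: float = 0.01,
    count_term=lambda m: 2.0 / m,
) -> float:
    """Phenotype-specific MAF threshold for polygenic-score variants.

    ``max(floor, count_term(min(n_cases, n_controls)))`` with the
    count-dependent term configurable (default ``2 / min``, a guard
    against variants observed only a handful of times in the smaller arm).
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return max(floor, count_term(min(n_cases, n_controls)))
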