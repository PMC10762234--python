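"""Per-taxon drought-response count models under the nested field design.

The model of record for one taxon at one timepoint is a count regression of the
taxon's reads on the drought treatment with field-level intercepts absorbing
the region/site/field nesting (a within-field contrast, consistent with nested
random intercepts on a balanced design), and ``log(library size)`` as offset so
the treatment coefficient is a log relative-abundance effect.

Family choice (negative binomial / Poisson / binomial presence-absence) follows
simulation-based quantile-residual diagnostics: simulate replicate datasets from
the fitted model, compute per-observation mid-p ECDF residuals, and test their
uniformity with a Kolmogorov-Smirnov test. A stratified sign-flip permutation
test on paired plot differences serves as the design-respecting fallback and
cross-check.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

FAMILIES = ("negative_binomial", "poisson", "binomial")
FAMILY_TRIAL_ORDER = ("negative_binomial", "poisson", "binomial")

_MIN_ALPHA = 1e-8  # NB dispersion floor; below this the fit is effectively Poisson


class DegenerateTaxonError(ValueError):
    """Raised for taxa whose counts carry no information (all zero)."""


@dataclass
class FamilyDiagnostics:
    """Simulation-based residual diagnostics for one candidate family."""

    family: str
    ks_statistic: float
    ks_pvalue: float
    residuals: np.ndarray = dc_field(repr=False, default=None)


class TaxonResponseResults:
    """Fitted drought-response contrast for one taxon.

    Attributes
    ----------
    taxon_id : str
    family : str
        Count family of the selected fit.
    params : pandas.Series
        All regression coefficients (field intercepts + treatment).
    treatment_coefficient : float
        Log-scale drought effect; > 0 means higher abundance under drought.
    bse : float
        Standard error of the treatment coefficient.
    p_value : float or nan
        Two-sided p-value (t reference, df = n_obs - n_params); nan when the
        fit did not converge.
    converged : bool
    diagnostics : FamilyDiagnostics or None
        Residual-uniformity statistic of the selected family.
    n_obs : int
    """

    def __init__(self, model, family, params, cov_index, treatment_coefficient,
                 bse, p_value, converged, diagnostics, nb_alpha=None):
        self.model = model
        self.taxon_id = model.taxon_id
        self.family = family
        self.params = params
        self._cov_index = cov_index
        self.treatment_coefficient = treatment_coefficient
        self.bse = bse
        self.p_value = p_value
        self.converged = converged
        self.diagnostics = diagnostics
        self.nb_alpha = nb_alpha
        self.n_obs = model.n_obs

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            f"Taxon drought-response model: {self.taxon_id}",
            "=" * 46,
            f"family:            {self.family}",
            f"n_obs:             {self.n_obs}",
            f"converged:         {self.converged}",
            f"treatment coef:    {self.treatment_coefficient:+.4f}"
            if np.isfinite(self.treatment_coefficient) else "treatment coef:    nan",
            f"std err:           {self.bse:.4f}" if np.isfinite(self.bse) else "std err:           nan",
            f"p-value (2-sided): {self.p_value:.4g}" if np.isfinite(self.p_value) else "p-value:           nan",
        ]
        if self.nb_alpha is not None:
            lines.append(f"NB dispersion:     {self.nb_alpha:.4f}")
        if d is not None:
            lines.append(f"residual KS:       D={d.ks_statistic:.3f}, p={d.ks_pvalue:.3f}")
        return "\n".join(lines)


class TaxonResponseModel:
    """Count model for one taxon's drought response at one timepoint.

    Parameters
    ----------
    counts : pandas.Series
        Reads for the taxon, indexed by sample id.
    design : pandas.DataFrame
        Sample metadata restricted to one timepoint (must contain ``field`` and
        ``treatment``; both treatment levels present).
    library_size : pandas.Series or int, optional
        Per-sample totals for the count-family offset. For rarefied tables this
        is the constant rarefaction depth. Defaults to 1 (no offset).
    family : str, optional
        Force one of ``negative_binomial | poisson | binomial``; default is
        simulation-based selection (see :func:`select_family`).
    taxon_id : str
    """

    def __init__(self, counts: pd.Series, design: pd.DataFrame,
                 library_size=None, family: str | None = None,
                 taxon_id: str = "taxon", m_sim: int = 250,
                 diag_alpha: float = 0.05, seed: int = 0):
        if design["timepoint"].nunique() > 1:
            raise ValueError("design must be restricted to a single timepoint")
        if design["treatment"].nunique() < 2:
            raise ValueError("both treatment levels must be present")
        if family is not None and family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        counts = counts.reindex(design.index)
        if counts.isna().any():
            raise KeyError("counts missing for some design samples")
        y = counts.to_numpy(dtype=float)
        if not y.any():
            raise DegenerateTaxonError(f"all-zero counts: degenerate taxon {taxon_id!r}")
        self.taxon_id = taxon_id
        self.y = y
        self.design = design
        self.family = family
        self.m_sim = m_sim
        self.diag_alpha = diag_alpha
        self.seed = seed
        self.n_obs = len(y)
        fields = pd.get_dummies(design["field"], dtype=float)
        self._field_names = [f"field[{c}]" for c in fields.columns]
        self.treatment = (design["treatment"] == "drought").to_numpy(dtype=float)
        self.exog = np.column_stack([fields.to_numpy(), self.treatment])
        self.exog_names = self._field_names + ["treatment[drought]"]
        if library_size is None:
            lib = np.ones(self.n_obs)
        elif np.isscalar(library_size):
            lib = np.full(self.n_obs, float(library_size))
        else:
            lib = pd.Series(library_size).reindex(design.index).to_numpy(dtype=float)
        self.offset = np.log(lib)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> TaxonResponseResults:
        """Fit the selected (or forced) family and return the treatment contrast."""
        if self.family is not None:
            fam = self.family
            fit, alpha = self._fit_family(fam)
            diag = self._diagnose(fam, fit, alpha) if fit is not None else None
        else:
            fam, fit, alpha, diag = self._select()
        return self._package(fam, fit, alpha, diag)

    def _select(self):
        # binary-like data cannot inform a count family
        if self.y.max() <= 1:
            fit, alpha = self._fit_family("binomial")
            diag = self._diagnose("binomial", fit, alpha) if fit is not None else None
            return "binomial", fit, alpha, diag
        tried = []
        for fam in FAMILY_TRIAL_ORDER:
            fit, alpha = self._fit_family(fam)
            if fit is None:
                continue
            diag = self._diagnose(fam, fit, alpha)
            tried.append((fam, fit, alpha, diag))
            if diag.ks_pvalue >= self.diag_alpha:
                return fam, fit, alpha, diag
        if not tried:
            return FAMILY_TRIAL_ORDER[0], None, None, None
        return max(tried, key=lambda t: t[3].ks_pvalue)

    def _fit_family(self, fam):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                if fam == "poisson":
                    return self._fit_glm(sm.families.Poisson(), self.offset), None
                if fam == "negative_binomial":
                    return self._fit_nb()
                if fam == "binomial":
                    yb = (self.y > 0).astype(float)
                    if yb.min() == yb.max():
                        return None, None
                    res = sm.GLM(yb, self.exog, family=sm.families.Binomial()).fit(
                        maxiter=100)
                    if not np.all(np.isfinite(res.bse)):
                        return None, None
                    return res, None
            except Exception:
                return None, None

    def _fit_conditional_logit(self):
        """Treatment effect on presence/absence, field intercepts eliminated by
        conditioning (the calibrated choice when strata are many and small)."""
        from statsmodels.discrete.conditional_models import ConditionalLogit
        yb = (self.y > 0).astype(float)
        groups = self.design["field"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ConditionalLogit(yb, self.treatment[:, None], groups=groups).fit(disp=0)
        if not np.all(np.isfinite(res.bse)) or res.bse[0] <= 0:
            raise RuntimeError("conditional logit: unstable fit")
        return res

    def _fit_glm(self, family, offset):
        res = sm.GLM(self.y, self.exog, family=family, offset=offset).fit(maxiter=100)
        if not np.all(np.isfinite(res.bse)):
            raise RuntimeError("non-finite standard errors")
        return res

    def _fit_nb(self):
        """Iterated GLM fit of the NB model with dispersion alpha profiled by
        Cox-Reid adjusted likelihood (the adjustment removes the downward bias
        from the many field intercepts, cf. dispersion estimation in edgeR)."""
        y = self.y
        X = self.exog

        def profile_alpha(mu):
            def nll(log_a):
                a = np.exp(log_a)
                k = 1.0 / a
                ll = np.sum(
                    gammaln(y + k) - gammaln(k)
                    + k * np.log(k / (k + mu))
                    + y * np.log(mu / (k + mu) + 1e-300)
                )
                w = mu / (1.0 + a * mu)  # working weights, log link
                _, logdet = np.linalg.slogdet((X * w[:, None]).T @ X)
                return -(ll - 0.5 * logdet)
            r = minimize_scalar(nll, bounds=(np.log(_MIN_ALPHA), 5.0), method="bounded")
            return float(np.exp(r.x))

        res = self._fit_glm(sm.families.Poisson(), self.offset)
        alpha = profile_alpha(res.mu)
        for _ in range(8):
            if alpha <= _MIN_ALPHA * 1.01:
                # collapses to Poisson; keep NB label (NB nests Poisson)
                return self._fit_glm(sm.families.Poisson(), self.offset), _MIN_ALPHA
            res = self._fit_glm(sm.families.NegativeBinomial(alpha=alpha), self.offset)
            new = profile_alpha(res.mu)
            if abs(np.log(new) - np.log(alpha)) < 1e-4:
                alpha = new
                break
            alpha = new
        return res, alpha

    # -- diagnostics -----------------------------------------------------

    def simulate_fitted(self, fam, fit, alpha, m, rng) -> np.ndarray:
        """Draw ``m`` replicate response vectors from the fitted model (m x n)."""
        mu = fit.mu
        if fam == "binomial":
            return (rng.random((m, self.n_obs)) < mu).astype(float)
        if fam == "poisson" or alpha is None or alpha <= _MIN_ALPHA * 1.01:
            return rng.poisson(mu, size=(m, self.n_obs)).astype(float)
        k = 1.0 / alpha
        lam = rng.gamma(k, mu / k, size=(m, self.n_obs))
        return rng.poisson(lam).astype(float)

    def _diagnose(self, fam, fit, alpha) -> FamilyDiagnostics:
        """DHARMa-style simulated quantile residuals + KS uniformity test."""
        rng = np.random.default_rng(self.seed + 1)
        sims = self.simulate_fitted(fam, fit, alpha, self.m_sim, rng)
        obs = (self.y > 0).astype(float) if fam == "binomial" else self.y
        below = (sims < obs).mean(axis=0)
        ties = (sims == obs).mean(axis=0)
        # randomized quantile residual: uniform under the fitted model even for
        # heavily discrete counts (a fixed jitter seed keeps fits reproducible)
        resid = below + rng.random(self.n_obs) * ties
        ks = scipy.stats.kstest(resid, "uniform")
        return FamilyDiagnostics(fam, float(ks.statistic), float(ks.pvalue), resid)

    # -- packaging -------------------------------------------------------

    def _package(self, fam, fit, alpha, diag) -> TaxonResponseResults:
        if fit is None:
            return TaxonResponseResults(
                self, fam, None, None, np.nan, np.nan, np.nan, False, diag, alpha)
        j = len(self.exog_names) - 1
        if fam == "binomial":
            # inference from the conditional likelihood (field intercepts
            # eliminated exactly); the GLM fit is kept for simulation
            try:
                cond = self._fit_conditional_logit()
                coef, se = float(cond.params[0]), float(cond.bse[0])
            except Exception:
                coef, se = np.nan, np.nan
        else:
            coef = float(fit.params[j])
            se = float(fit.bse[j])
        df = max(self.n_obs - len(self.exog_names), 1)
        tstat = coef / se if se > 0 else np.nan
        p = float(2 * scipy.stats.t.sf(abs(tstat), df)) if np.isfinite(tstat) else np.nan
        converged = bool(np.isfinite(coef) and np.isfinite(se) and se > 0
                         and getattr(fit, "converged", True))
        params = pd.Series(np.asarray(fit.params), index=self.exog_names)
        return TaxonResponseResults(
            self, fam, params, None, coef, se,
            p if converged else np.nan, converged, diag, alpha)


def fit_taxon_model(counts, design, family=None, library_size=None,
                    taxon_id="taxon", seed=0) -> TaxonResponseResults:
    """Functional wrapper: build a :class:`TaxonResponseModel` and fit it."""
    return TaxonResponseModel(
        counts, design, library_size=library_size, family=family,
        taxon_id=taxon_id, seed=seed).fit()


def select_family(counts, design, library_size=None, seed=0,
                  m_sim: int = 250, diag_alpha: float = 0.05) -> str:
    """Pick the count family by simulation-based residual diagnostics.

    Trial order negative_binomial -> poisson -> binomial; the first family whose
    residual-uniformity KS test is not rejected at ``diag_alpha`` wins; if all
    are rejected, the family with the largest uniformity p-value is returned.
    """
    model = TaxonResponseModel(counts, design, library_size=library_size,
                               m_sim=m_sim, diag_alpha=diag_alpha, seed=seed)
    fam, _, _, _ = model._select()
    return fam


# -- stratified permutation test ----------------------------------------


def _paired_differences(values: pd.Series, design: pd.DataFrame) -> np.ndarray:
    """Drought-minus-control differences per (field, pair) stratum."""
    df = design.copy()
    df["value"] = values.reindex(design.index).to_numpy()
    if df["value"].isna().any():
        raise KeyError("values missing for some design samples")
    wide = df.pivot_table(index=["field", "pair"], columns="treatment",
                          values="value", aggfunc="mean")
    if "drought" not in wide.columns or "control" not in wide.columns:
        raise ValueError("need both drought and control samples")
    wide = wide.dropna()
    return (wide["drought"] - wide["control"]).to_numpy()


def permutation_test(values: pd.Series, design: pd.DataFrame,
                     n_perm: int = 999, seed: int = 0,
                     exhaustive: bool = False) -> tuple[float, float]:
    """Stratified sign-flip permutation test of the drought effect.

    The statistic is the mean drought-minus-control difference of ``values``
    (per-sample relative abundances) over (field, pair) strata; the null is
    generated by independently swapping treatment labels within each stratum.

    Returns ``(statistic, two_sided_p)``. Monte-Carlo p uses the add-one rule
    ``(1 + #{|T*| >= |T|}) / (1 + n_perm)``; with ``exhaustive=True`` all
    ``2^S`` sign patterns are enumerated and p is the exact tail fraction.
    """
    d = _paired_differences(values, design)
    n_strata = len(d)
    if n_strata < 1:
        raise ValueError("no complete drought/control strata")
    t_obs = d.mean()
    if exhaustive:
        if n_strata > 20:
            raise ValueError("exhaustive enumeration limited to <= 20 strata")
        hits = 0
        total = 2 ** n_strata
        for signs in itertools.product((1.0, -1.0), repeat=n_strata):
            t_star = float(np.dot(signs, d)) / n_strata
            if abs(t_star) >= abs(t_obs) - 1e-12:
                hits += 1
        return float(t_obs), hits / total
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_strata))
    t_star = signs @ d / n_strata
    hits = int((np.abs(t_star) >= abs(t_obs) - 1e-12).sum())
    return float(t_obs), (1 + hits) / (1 + n_perm)
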