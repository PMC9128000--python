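"""Allelic-effect statistics on module expression counts and keystone features.

Per-mouse module counts are modeled with Poisson log-link GLMs.  Genotype
screens fit ``counts ~ genotype``; parent-of-origin analyses fit
``counts ~ cross + genotype + cross:genotype`` with sequential (Type I)
analysis of deviance.  Effects classify as:

* generalized parental — significant cross main effect, no interaction;
* genetic — significant genotype main effect, no interaction;
* putative imprinting — significant cross x genotype interaction.

Goodness of fit is an upper-tail chi-square of the residual deviance at the
residual degrees of freedom (pass iff p > 0.05).  Categorical enrichments use
Fisher's exact test (exact for 2x2; Monte Carlo over margin-fixed tables for
larger ones).  Keystone post-tests are het-vs-wildtype contrasts from a
one-way linear model, Bonferroni-adjusted over the three mutant genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import gammaln

from .fdr import estimate_pi0, qvalues  # noqa: F401 - shared FDR machinery re-exported

__all__ = [
    "ModuleCountMatrix",
    "GlmResult",
    "ContingencyResult",
    "count_module_expression",
    "variance_filter",
    "fit_genotype_glm",
    "fit_imprinting_glm",
    "classify_effect",
    "fisher_exact",
    "profile_fisher",
    "keystone_tests",
    "tally_significance_dependence",
    "link_modules_to_keystones",
]

GENOTYPES = ("wildtype", "Th het", "Ddc het", "ThDdc het")
CROSSES = ("maternal", "paternal")


@dataclass
class ModuleCountMatrix:
    """Mice x modules integer counts plus per-mouse design metadata."""

    counts: pd.DataFrame  # index: mouse id, columns: module ids
    metadata: pd.DataFrame  # index: mouse id; genotype, cross, sex, phase

    def __post_init__(self):
        c = self.counts.to_numpy()
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("module counts must be non-negative integers")
        if not self.counts.index.equals(self.metadata.index):
            raise ValueError("counts and metadata must share the mouse index")


@dataclass
class ContingencyResult:
    table: np.ndarray
    p: float
    method: str  # "exact" | "monte_carlo"
    odds_ratio: float | None = None
    seed: int | None = None
    iterations: int | None = None


@dataclass
class GlmResult:
    """Per-module analysis-of-deviance results."""

    module: object
    term_p: dict
    gof_p: float
    coefficients: pd.Series | None = None
    flags: list = field(default_factory=list)

    @property
    def gof_pass(self) -> bool:
        return self.gof_p > 0.05


def count_module_expression(assignments: pd.DataFrame, metadata: pd.DataFrame,
                            phase: str | None = None) -> ModuleCountMatrix:
    """Tally module expression per mouse (zero rows for excursion-less mice).

    ``assignments`` needs ``mouse``, ``module`` and (if ``phase`` is given)
    ``phase`` columns; ``metadata`` is indexed by mouse id.
    """
    df = assignments
    if phase is not None:
        df = df[df["phase"] == phase]
    unknown = set(df["mouse"]) - set(metadata.index)
    if unknown:
        raise ValueError(f"assignments reference unknown mice: {sorted(unknown)[:5]}")
    modules = sorted(df["module"].unique())
    counts = (
        df.groupby(["mouse", "module"]).size().unstack(fill_value=0)
        .reindex(index=metadata.index, columns=modules, fill_value=0)
        .astype(int)
    )
    md = metadata if phase is None else metadata.assign(phase=phase)
    return ModuleCountMatrix(counts=counts, metadata=md)


def variance_filter(counts: ModuleCountMatrix | pd.DataFrame,
                    min_variance: float) -> tuple[pd.DataFrame, list]:
    """Drop modules whose across-mouse count variance falls below threshold."""
    if min_variance < 0:
        raise ValueError("min_variance must be >= 0")
    df = counts.counts if isinstance(counts, ModuleCountMatrix) else counts
    var = df.var(axis=0, ddof=1)
    retained = var.index[var >= min_variance].tolist()
    return df[retained], retained


# --- Poisson GLMs -----------------------------------------------------------

def _poisson_fit(y: np.ndarray, X: np.ndarray):
    model = sm.GLM(y, X, family=sm.families.Poisson())
    return model.fit()


def _design(factors: dict) -> tuple[np.ndarray, list]:
    """Treatment-coded design matrix with sequential term column blocks."""
    n = len(next(iter(factors.values())))
    cols = [np.ones(n)]
    names = ["intercept"]
    blocks = {}
    for term, values in factors.items():
        if ":" in term:
            a, b = term.split(":")
            block = []
            for ca in blocks[a]:
                for cb in blocks[b]:
                    cols.append(ca * cb)
                    names.append(term)
                    block.append(ca * cb)
            blocks[term] = block
        else:
            values = pd.Series(values).astype(str)
            levels = sorted(values.unique())
            block = []
            for lev in levels[1:]:
                ind = (values == lev).to_numpy(dtype=float)
                cols.append(ind)
                names.append(term)
                block.append(ind)
            blocks[term] = block
    return np.column_stack(cols), names


def _sequential_anova(y: np.ndarray, factors: dict) -> tuple[dict, object]:
    """Sequential (Type I) analysis of deviance for a Poisson GLM.

    Returns per-term chi-square p-values and the full-model fit.
    """
    X_full, names = _design(factors)
    terms = list(dict.fromkeys(n for n in names if n != "intercept"))
    deviances, dfs = [], []
    fitted = None
    for k in range(len(terms) + 1):
        included = ["intercept"] + terms[:k]
        idx = [i for i, n in enumerate(names) if n in included]
        fitted = _poisson_fit(y, X_full[:, idx])
        deviances.append(fitted.deviance)
        dfs.append(len(idx))
    term_p = {}
    for k, term in enumerate(terms):
        ddev = deviances[k] - deviances[k + 1]
        ddf = dfs[k + 1] - dfs[k]
        term_p[term] = float(sps.chi2.sf(max(ddev, 0.0), ddf)) if ddf else 1.0
    return term_p, fitted


def fit_genotype_glm(counts, genotype) -> GlmResult:
    """Poisson GLM genotype screen for one module: counts ~ genotype.

    The genotype term is tested by analysis of deviance against the
    intercept-only model; GOF is the residual-deviance chi-square.
    """
    y = np.asarray(counts, dtype=float)
    genotype = pd.Series(genotype).astype(str)
    if genotype.nunique() < 2:
        raise ValueError("need >= 2 genotype levels")
    if np.all(y == 0):
        return GlmResult(module=None, term_p={"genotype": 1.0}, gof_p=1.0,
                         flags=["degenerate: all-zero counts"])
    term_p, fitted = _sequential_anova(y, {"genotype": genotype})
    gof = float(sps.chi2.sf(fitted.deviance, fitted.df_resid))
    return GlmResult(module=None, term_p=term_p, gof_p=gof,
                     coefficients=pd.Series(fitted.params))


def fit_imprinting_glm(counts, cross, genotype) -> GlmResult:
    """Parent-of-origin Poisson GLM: counts ~ cross + genotype + cross:genotype.

    Sequential analysis of deviance gives p-values for the cross and genotype
    main effects and their interaction.  An empty cross x genotype cell makes
    the interaction inestimable (flagged).
    """
    y = np.asarray(counts, dtype=float)
    cross = pd.Series(cross).astype(str)
    genotype = pd.Series(genotype).astype(str)
    if cross.nunique() < 2 or genotype.nunique() < 2:
        raise ValueError("need both crosses and >= 2 genotypes")
    flags = []
    cells = pd.crosstab(cross, genotype)
    if (cells == 0).any().any() or cells.shape[0] * cells.shape[1] < \
            cross.nunique() * genotype.nunique():
        flags.append("confounded: empty cross x genotype cell")
        term_p, fitted = _sequential_anova(
            y, {"cross": cross, "genotype": genotype})
        term_p["cross:genotype"] = np.nan
    else:
        term_p, fitted = _sequential_anova(
            y, {"cross": cross, "genotype": genotype,
                "cross:genotype": None})
        # interaction block built from the main-effect blocks
    gof = float(sps.chi2.sf(fitted.deviance, fitted.df_resid))
    res = GlmResult(module=None, term_p=term_p, gof_p=gof,
                    coefficients=pd.Series(fitted.params), flags=flags)
    return res


def classify_effect(p_cross: float, p_genotype: float, p_interaction: float,
                    alpha: float = 0.05) -> frozenset:
    """Label allelic effects from the three sequential deviance p-values."""
    labels = set()
    inter = (not np.isnan(p_interaction)) and p_interaction < alpha
    if inter:
        labels.add("putative imprinting")
    else:
        if p_cross < alpha:
            labels.add("generalized parental")
        if p_genotype < alpha:
            labels.add("genetic")
    return frozenset(labels)


# --- Fisher tests -----------------------------------------------------------

def _table_logprob(t: np.ndarray) -> float:
    """Log-probability of a table under fixed margins (hypergeometric family)."""
    t = np.asarray(t, dtype=float)
    return float(
        gammaln(t.sum(axis=1) + 1).sum() + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(t.sum() + 1) - gammaln(t + 1).sum()
    )


def fisher_exact(table, mc_iterations: int = 100_000,
                 seed=None) -> ContingencyResult:
    """Fisher's exact test of independence for an r x c count table.

    2x2 tables are exact (two-sided, summing hypergeometric probabilities of
    tables no more probable than the observed one).  Larger tables use a
    Monte Carlo p over margin-preserving sampled tables with the add-one
    estimator, as exact enumeration is infeasible for the module-profile
    tables used here.
    """
    t = np.asarray(table, dtype=np.int64)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    if t.shape == (2, 2):
        odds, p = sps.fisher_exact(t, alternative="two-sided")
        return ContingencyResult(table=t, p=float(p), method="exact",
                                 odds_ratio=float(odds))
    if t.size == 1 or 1 in t.shape:
        return ContingencyResult(table=t, p=1.0, method="exact")
    rng = np.random.default_rng(seed)
    dist = sps.random_table(t.sum(axis=1), t.sum(axis=0))
    obs_lp = _table_logprob(t)
    sampled = dist.rvs(mc_iterations, method="patefield", random_state=rng)
    lps = np.array([_table_logprob(s) for s in sampled])
    p = (1 + int((lps <= obs_lp + 1e-7).sum())) / (mc_iterations + 1)
    return ContingencyResult(table=t, p=float(p), method="monte_carlo",
                             seed=seed, iterations=mc_iterations)


def profile_fisher(table, mc_iterations: int = 100_000,
                   seed=None) -> ContingencyResult:
    """Module-profile dependence test: modules x 2 genotype count table."""
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("profile table must be modules x 2")
    keep = t.sum(axis=1) > 0
    return fisher_exact(t[keep], mc_iterations=mc_iterations, seed=seed)


def tally_significance_dependence(table) -> ContingencyResult:
    """2x2 Fisher on tallies of significant features/modules by sex x parent."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("tally table must be 2x2")
    return fisher_exact(t)


# --- keystone linear models -------------------------------------------------

def keystone_tests(keystones: pd.DataFrame, genotype, cross, sex,
                   reference: str = "wildtype") -> pd.DataFrame:
    """Genotype linear models per keystone feature within sex x cross subsets.

    For each feature and each (sex, cross) subset: one-way genotype OLS with
    an overall F test, plus het-vs-wildtype contrasts Bonferroni-adjusted
    over the mutant genotypes compared.  Subsets with singleton genotype
    groups are flagged and skipped.
    """
    genotype = pd.Series(np.asarray(genotype, dtype=object),
                         index=keystones.index).astype(str)
    cross = pd.Series(np.asarray(cross, dtype=object),
                      index=keystones.index).astype(str)
    sex = pd.Series(np.asarray(sex, dtype=object),
                    index=keystones.index).astype(str)
    rows = []
    for (sx, cr), idx in keystones.groupby([sex, cross]).groups.items():
        sub = keystones.loc[idx]
        g = genotype.loc[idx]
        sizes = g.value_counts()
        if (sizes < 2).any() or reference not in sizes.index or len(sizes) < 2:
            rows.append({"sex": sx, "cross": cr, "feature": None,
                         "flag": "singleton or missing genotype group"})
            continue
        muts = [lev for lev in sizes.index if lev != reference]
        m = len(muts)
        levels = [reference] + sorted(muts)
        X = np.column_stack(
            [np.ones(len(g))] + [(g == lev).to_numpy(float) for lev in levels[1:]])
        for feature in sub.columns:
            y = sub[feature].to_numpy(dtype=float)
            fit = sm.OLS(y, X).fit()
            fp = float(fit.f_pvalue) if not np.isnan(fit.f_pvalue) else 1.0
            for j, lev in enumerate(levels[1:], start=1):
                raw = float(fit.pvalues[j])
                rows.append({
                    "sex": sx, "cross": cr, "feature": feature,
                    "genotype": lev, "main_effect_p": fp,
                    "contrast_p": raw,
                    "contrast_p_bonferroni": min(1.0, raw * m),
                    "estimate": float(fit.params[j]),
                    "flag": "",
                })
    return pd.DataFrame(rows)


def link_modules_to_keystones(counts: ModuleCountMatrix | pd.DataFrame,
                              keystones: pd.DataFrame,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Simple regressions of each keystone feature on each module's counts.

    Reports Pearson r, slope sign and p per (module, feature) across mice;
    zero-variance pairs are skipped.
    """
    cdf = counts.counts if isinstance(counts, ModuleCountMatrix) else counts
    common = cdf.index.intersection(keystones.index)
    if len(common) < 3:
        raise ValueError("need >= 3 mice shared between tables")
    cdf, kdf = cdf.loc[common], keystones.loc[common]
    rows = []
    for module in cdf.columns:
        x = cdf[module].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        for feature in kdf.columns:
            y = kdf[feature].to_numpy(dtype=float)
            if y.std() == 0:
                continue
            r, p = sps.pearsonr(x, y)
            rows.append({"module": module, "feature": feature,
                         "pearson_r": float(r), "slope_sign": int(np.sign(r)),
                         "p": float(p), "significant": bool(p < alpha)})
    return pd.DataFrame(rows)
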