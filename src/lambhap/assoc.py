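"""Association modelling: presence/absence, adjusted and diplotype series.

Three model series are fitted per trait, mirroring a candidate-gene
association workflow in livestock:

1. *single* — a linear model of the trait on the presence (1) or absence
   (0) of one haplotype in an animal's diplotype, with the trait's
   structural fixed factors and sire as a random intercept;
2. *adjusted* — the same model with every other haplotype whose single
   model gave p < 0.20 co-fitted, isolating independent effects;
3. *diplotype* — diplotype as a fixed factor over the diplotypes exceeding
   a 5% frequency in the analysed subset, with least-significant-difference
   pairwise comparisons, Bonferroni-corrected, summarised as a compact
   letter display.

Group summaries are estimated marginal means: model predictions averaged
with equal weight over the levels of the other fixed factors, covariates
held at their observed means.  The random sire intercept is estimated by
REML; when the sire variance collapses to zero the model degrades to an
ordinary least-squares fit and the result is flagged.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genodata import (CARCASS_TRAITS, PHENOTYPE_FIELDS, AnimalRecord,
                       Diplotype, Gender, Haplotype)
from .phasing import CohortPhasing

__all__ = [
    "ModelSpec", "TraitModel", "TRAIT_MODELS", "AssociationResult",
    "DiplotypeResult", "build_dataset", "code_presence",
    "select_structure_term", "fit_presence_model", "fit_adjusted_model",
    "fit_diplotype_model", "run_single_series", "run_adjusted_series",
    "classify_significance", "Significance", "derived_growth_effect",
    "derived_meat_effect", "letter_display",
]


@dataclass(frozen=True)
class ModelSpec:
    """Thresholds governing the three model series."""

    alpha: float = 0.05            # significance level
    include_p: float = 0.20        # co-fit screen for the adjusted series
    diplotype_min_freq: float = 0.05
    haplotype_min_freq: float = 0.05  # haplotypes assessed in series 1/2

    def __post_init__(self) -> None:
        for v in (self.alpha, self.include_p, self.diplotype_min_freq):
            if not 0 < v < 1:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class TraitModel:
    """Structural terms fitted alongside the focal genetic term.

    ``factors`` are categorical fixed effects, ``covariates`` continuous
    ones; carcass traits are measured on slaughtered males only.
    """

    factors: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    males_only: bool = False


# Per-trait structure: birth weight is adjusted for conditions at birth;
# pre-weaning weights and growth for rearing conditions (and age where the
# measurement age varies); carcass traits for rearing rank and slaughter
# age, on the male slaughter cohort.
TRAIT_MODELS: dict[str, TraitModel] = {
    "birth_weight": TraitModel(("gender", "birth_rank")),
    "tailing_weight": TraitModel(("gender", "rearing_rank"), ("age_weaning",)),
    "weaning_weight": TraitModel(("gender", "rearing_rank"), ("age_weaning",)),
    "growth_rate": TraitModel(("gender", "rearing_rank")),
    **{t: TraitModel(("rearing_rank",), ("age_slaughter",), males_only=True)
       for t in sorted(CARCASS_TRAITS)},
}

GROWTH_TRAITS = tuple(t for t in PHENOTYPE_FIELDS if t not in CARCASS_TRAITS)


def code_presence(diplotype: Diplotype, haplotype: Haplotype) -> int:
    """1 if the haplotype occurs in the diplotype (once or twice), else 0."""
    return int(diplotype.contains(haplotype))


class Significance(str, enum.Enum):
    SIGNIFICANT = "significant"
    TREND = "trend"
    NS = "ns"


def classify_significance(p: float, alpha: float = 0.05,
                          trend: float = 0.20) -> Significance:
    """p < alpha is significant; alpha <= p < trend is a trend (the
    boundary p == alpha counts as a trend, per the strict inequality)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < alpha:
        return Significance.SIGNIFICANT
    if p < trend:
        return Significance.TREND
    return Significance.NS


def derived_growth_effect(emm_absent: float, emm_present: float,
                          days: float) -> tuple[float, float]:
    """Per-day growth difference (absent − present, g/day) and its
    cumulative weight consequence over ``days`` days (g)."""
    if days <= 0:
        raise ValueError("days must be positive")
    diff = emm_absent - emm_present
    return diff, diff * days


def derived_meat_effect(yield_diff_pct: float, carcass_weight_kg: float) -> int:
    """Grams of lean meat implied by a lean-yield difference (percentage
    points of carcass weight) on a carcass of the given weight."""
    if carcass_weight_kg <= 0:
        raise ValueError("carcass weight must be positive")
    return round(carcass_weight_kg * 1000.0 * yield_diff_pct / 100.0)


# ---------------------------------------------------------------------------
# Dataset assembly

FACTOR_COLUMNS = ("gender", "birth_rank", "rearing_rank")


def build_dataset(records: Sequence[AnimalRecord],
                  phasing: Optional[CohortPhasing | dict] = None,
                  ) -> pd.DataFrame:
    """Flatten records (plus phased diplotypes) into the modelling frame.

    ``phasing`` may be a :class:`CohortPhasing` or a plain
    ``animal_id -> Diplotype`` mapping (e.g. a simulation truth table).
    One row per progeny; ``diplotype`` is None for unresolved animals,
    which every model drops.
    """
    if phasing is None:
        resolved: dict[str, Diplotype] = {}
    elif isinstance(phasing, dict):
        resolved = phasing
    else:
        resolved = phasing.resolved
    rows = []
    for r in records:
        if r.sire_id is None:
            continue
        row = {
            "animal_id": r.animal_id,
            "sire": r.sire_id,
            "gender": r.gender.value,
            "birth_rank": r.birth_rank.value,
            "rearing_rank": r.rearing_rank.value,
            "age_weaning": r.age_weaning,
            "age_slaughter": r.age_slaughter,
            "diplotype": resolved.get(r.animal_id),
        }
        for t in PHENOTYPE_FIELDS:
            row[t] = r.phenotypes.get(t)
        rows.append(row)
    df = pd.DataFrame(rows)
    for t in PHENOTYPE_FIELDS + ("age_weaning", "age_slaughter"):
        df[t] = pd.to_numeric(df[t], errors="coerce")
    return df


def cohort_haplotypes(df: pd.DataFrame, min_freq: float = 0.05
                      ) -> list[Haplotype]:
    """Haplotypes whose chromosome-count frequency among resolved animals
    reaches ``min_freq``, in descending frequency order."""
    counts: dict[Haplotype, int] = {}
    n = 0
    for d in df["diplotype"]:
        if d is None:
            continue
        n += 1
        for h in d.haplotypes:
            counts[h] = counts.get(h, 0) + 1
    return [h for h, c in sorted(counts.items(),
                                 key=lambda kv: (-kv[1], kv[0]))
            if c / (2 * n) >= min_freq]


# ---------------------------------------------------------------------------
# Linear model engine


class NotEstimableError(ValueError):
    pass


@dataclass
class DesignInfo:
    matrix: pd.DataFrame
    factor_levels: dict[str, list[str]]
    covariate_means: dict[str, float]
    dropped_factors: tuple[str, ...]


def _build_design(df: pd.DataFrame, factors: Sequence[str],
                  covariates: Sequence[str],
                  focal: Optional[pd.DataFrame] = None) -> DesignInfo:
    """Treatment-coded design matrix with intercept.  Factors left with a
    single observed level are dropped (they are not estimable and carry no
    information on this subset)."""
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    levels: dict[str, list[str]] = {}
    dropped = []
    for f in factors:
        obs = sorted(df[f].dropna().unique())
        if len(obs) < 2:
            dropped.append(f)
            continue
        levels[f] = obs
        for lvl in obs[1:]:
            X[f"{f}[{lvl}]"] = (df[f] == lvl).astype(float)
    means: dict[str, float] = {}
    for c in covariates:
        vals = df[c].astype(float)
        means[c] = float(vals.mean())
        X[c] = vals
    if focal is not None:
        for c in focal.columns:
            X[c] = focal[c].astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise NotEstimableError(
            f"singular design: {X.shape[1] - rank} dependent column(s) among "
            + ", ".join(X.columns))
    return DesignInfo(X, levels, means, tuple(dropped))


@dataclass
class LinearFit:
    params: pd.Series
    cov: pd.DataFrame
    df_resid: float
    mixed: bool
    sire_variance: float
    notes: tuple[str, ...] = ()

    def _pt(self, stat: float) -> float:
        if self.mixed:
            return 2 * stats.norm.sf(abs(stat))
        return 2 * stats.t.sf(abs(stat), self.df_resid)

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """Estimate, SE and two-sided p of a linear combination c'beta."""
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov.to_numpy() @ c))
        p = self._pt(est / se) if se > 0 else 1.0
        return est, se, p

    def coef_p(self, name: str) -> float:
        c = np.zeros(len(self.params))
        c[self.params.index.get_loc(name)] = 1.0
        return self.contrast(c)[2]

    def joint_p(self, names: Sequence[str]) -> float:
        """Wald test that all named coefficients are zero (chi-square for
        the mixed fit, F for the OLS fallback)."""
        idx = [self.params.index.get_loc(n) for n in names]
        b = self.params.to_numpy()[idx]
        V = self.cov.to_numpy()[np.ix_(idx, idx)]
        w = float(b @ np.linalg.solve(V, b))
        q = len(idx)
        if self.mixed:
            return float(stats.chi2.sf(w, q))
        return float(stats.f.sf(w / q, q, self.df_resid))


def _fit_linear(y: pd.Series, design: DesignInfo,
                groups: Optional[pd.Series]) -> LinearFit:
    """REML random-intercept fit with OLS fallback.

    Falls back to fixed-effects-only when the group variance estimate is
    (numerically) zero, the optimiser fails, or no grouping is supplied;
    the fallback is recorded in ``notes``.
    """
    X = design.matrix
    yv = y.astype(float)
    notes: list[str] = []
    if groups is not None and groups.nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(yv, X, groups=groups).fit(reml=True)
            k = X.shape[1]
            sire_var = float(res.cov_re.iloc[0, 0])
            if res.converged and sire_var > 1e-8 * max(float(yv.var()), 1e-12):
                return LinearFit(
                    params=res.fe_params,
                    cov=res.cov_params().iloc[:k, :k],
                    df_resid=float(len(yv) - k),
                    mixed=True, sire_variance=sire_var)
            notes.append("sire variance estimated at zero; fixed-effects fit")
        except (np.linalg.LinAlgError, ValueError):
            notes.append("mixed fit failed; fixed-effects fit")
    res = sm.OLS(yv, X).fit()
    return LinearFit(params=res.params, cov=res.cov_params(),
                     df_resid=float(res.df_resid), mixed=False,
                     sire_variance=0.0, notes=tuple(notes))


def _emm_weights(design: DesignInfo, focal: dict[str, float]) -> np.ndarray:
    """Weight vector giving the estimated marginal mean for one focal cell:
    equal weight across factor-level combinations, covariates at means."""
    c = np.zeros(design.matrix.shape[1])
    for j, col in enumerate(design.matrix.columns):
        if col == "Intercept":
            c[j] = 1.0
        elif col in focal:
            c[j] = focal[col]
        elif col in design.covariate_means:
            c[j] = design.covariate_means[col]
        else:  # factor dummy "f[lvl]": averaged over levels with equal weight
            f = col[:col.index("[")]
            c[j] = 1.0 / len(design.factor_levels[f])
    return c


# ---------------------------------------------------------------------------
# Series 1 and 2: haplotype presence/absence


@dataclass
class AssociationResult:
    trait: str
    haplotype: Haplotype
    others: tuple[Haplotype, ...]      # co-fitted haplotypes (series 2)
    n_absent: int
    n_present: int
    emm_absent: Optional[float]
    se_absent: Optional[float]
    emm_present: Optional[float]
    se_present: Optional[float]
    p_value: Optional[float]
    effect: Optional[float] = None     # emm_present − emm_absent
    effect_se: Optional[float] = None  # SE of that difference
    status: str = "ok"                 # ok | not estimable | zero variance
    notes: tuple[str, ...] = ()

    @property
    def model_tag(self) -> str:
        return "single" if not self.others else (
            "adjusted(" + ",".join(h.display() for h in self.others) + ")")


def _trait_subset(df: pd.DataFrame, trait: str, model: TraitModel
                  ) -> pd.DataFrame:
    sub = df[df["diplotype"].notna() & df[trait].notna()]
    if model.males_only:
        sub = sub[sub["gender"] == Gender.MALE.value]
    for c in model.covariates:
        sub = sub[sub[c].notna()]
    return sub


def _presence_frame(sub: pd.DataFrame, haps: Sequence[Haplotype]
                    ) -> pd.DataFrame:
    return pd.DataFrame(
        {h.display(): [code_presence(d, h) for d in sub["diplotype"]]
         for h in haps}, index=sub.index)


def fit_presence_model(df: pd.DataFrame, trait: str, haplotype: Haplotype,
                       spec: ModelSpec = ModelSpec(),
                       others: Sequence[Haplotype] = (),
                       model: Optional[TraitModel] = None
                       ) -> AssociationResult:
    """Fit one presence/absence model and summarise it as estimated
    marginal means for the carrier and non-carrier groups.

    ``others`` co-fits additional presence terms (the adjusted series);
    with ``others`` empty this *is* the single-haplotype model.
    """
    model = model or TRAIT_MODELS[trait]
    sub = _trait_subset(df, trait, model)
    haps = [haplotype] + [h for h in others if h != haplotype]
    focal = _presence_frame(sub, haps)
    key = haplotype.display()
    n_present = int(focal[key].sum())
    n_absent = len(sub) - n_present
    base = dict(trait=trait, haplotype=haplotype, others=tuple(haps[1:]),
                n_absent=n_absent, n_present=n_present)
    if n_absent == 0 or n_present == 0:
        return AssociationResult(**base, emm_absent=None, se_absent=None,
                                 emm_present=None, se_present=None,
                                 p_value=None, status="not estimable")
    y = sub[trait].astype(float)
    if float(y.var()) == 0.0:
        v = float(y.iloc[0])
        return AssociationResult(**base, emm_absent=v, se_absent=0.0,
                                 emm_present=v, se_present=0.0, p_value=1.0,
                                 status="zero variance")
    design = _build_design(sub, model.factors, model.covariates, focal)
    fit = _fit_linear(y, design, sub["sire"])
    other_means = {h.display(): float(focal[h.display()].mean())
                   for h in haps[1:]}
    emms = {}
    weights = {}
    for val in (0.0, 1.0):
        c = _emm_weights(design, {key: val, **other_means})
        est, se, _ = fit.contrast(c)
        emms[val] = (est, se)
        weights[val] = c
    effect, effect_se, p = fit.contrast(weights[1.0] - weights[0.0])
    return AssociationResult(**base,
                             emm_absent=emms[0.0][0], se_absent=emms[0.0][1],
                             emm_present=emms[1.0][0], se_present=emms[1.0][1],
                             p_value=p, effect=effect, effect_se=effect_se,
                             notes=fit.notes)


def fit_adjusted_model(df: pd.DataFrame, trait: str, focal: Haplotype,
                       others: Sequence[Haplotype],
                       spec: ModelSpec = ModelSpec()) -> AssociationResult:
    """Series-2 model: the focal haplotype with the screened co-fits."""
    return fit_presence_model(df, trait, focal, spec, others=others)


def run_single_series(df: pd.DataFrame, traits: Sequence[str],
                      haplotypes: Sequence[Haplotype],
                      spec: ModelSpec = ModelSpec()
                      ) -> list[AssociationResult]:
    return [fit_presence_model(df, t, h, spec)
            for t in traits for h in haplotypes]


def run_adjusted_series(df: pd.DataFrame, singles: Sequence[AssociationResult],
                        spec: ModelSpec = ModelSpec()
                        ) -> list[AssociationResult]:
    """Screen the single series at p < ``include_p`` and refit every
    screened (trait, haplotype) with the other screened haplotypes
    co-fitted.  Traits with fewer than two screened haplotypes yield no
    adjusted models (nothing to adjust for)."""
    out: list[AssociationResult] = []
    by_trait: dict[str, list[AssociationResult]] = {}
    for r in singles:
        by_trait.setdefault(r.trait, []).append(r)
    for trait, results in by_trait.items():
        flagged = [r.haplotype for r in results
                   if r.p_value is not None and r.p_value < spec.include_p]
        if len(flagged) < 2:
            continue
        for h in flagged:
            others = [o for o in flagged if o != h]
            out.append(fit_adjusted_model(df, trait, h, others, spec))
    return out


# ---------------------------------------------------------------------------
# Series 3: diplotype models with pairwise comparisons


@dataclass
class DiplotypeResult:
    trait: str
    diplotypes: tuple[Diplotype, ...]
    n: tuple[int, ...]
    emm: tuple[float, ...]
    se: tuple[float, ...]
    letters: tuple[str, ...]
    overall_p: Optional[float]
    pairwise_p: pd.DataFrame          # Bonferroni-adjusted, symmetric
    status: str = "ok"
    notes: tuple[str, ...] = ()


def letter_display(n_groups: int, significant: set[tuple[int, int]]
                   ) -> list[str]:
    """Compact letter display by insert-and-absorb.

    Two groups share a letter iff their pair is not in ``significant``.
    """
    cols: list[set[int]] = [set(range(n_groups))]
    for i, j in sorted(significant):
        nxt: list[set[int]] = []
        for col in cols:
            if i in col and j in col:
                nxt.append(col - {j})
                nxt.append(col - {i})
            else:
                nxt.append(col)
        # absorb columns contained in another
        cols = [c for k, c in enumerate(nxt)
                if c and not any(c < o or (c == o and k2 < k)
                                 for k2, o in enumerate(nxt) if k2 != k)]
    cols.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(n_groups)]
    for letter, col in zip(alphabet, cols):
        for g in sorted(col):
            out[g] += letter
    return out


def fit_diplotype_model(df: pd.DataFrame, trait: str,
                        spec: ModelSpec = ModelSpec(),
                        model: Optional[TraitModel] = None) -> DiplotypeResult:
    """Fit diplotype as a fixed factor over the common diplotypes.

    The >5% frequency filter is computed on the trait's analysed subset so
    each trait's groups reflect its own sample.  The overall p-value is the
    Wald test of the diplotype term; pairwise LSD p-values are multiplied
    by the number of pairs (capped at 1) and rendered as letters.
    """
    model = model or TRAIT_MODELS[trait]
    sub = _trait_subset(df, trait, model)
    counts = sub["diplotype"].value_counts()
    keep = sorted((d for d, c in counts.items()
                   if c / len(sub) > spec.diplotype_min_freq))
    if len(keep) < 2:
        return DiplotypeResult(trait, tuple(keep),
                               tuple(int(counts.get(d, 0)) for d in keep),
                               (), (), (), None, pd.DataFrame(),
                               status="fewer than 2 diplotype groups")
    sub = sub[sub["diplotype"].isin(keep)]
    y = sub[trait].astype(float)
    labels = [d.display() for d in keep]
    dummies = pd.DataFrame(
        {f"dip[{lab}]": (sub["diplotype"] == d).astype(float)
         for d, lab in zip(keep[1:], labels[1:])}, index=sub.index)
    design = _build_design(sub, model.factors, model.covariates, dummies)
    fit = _fit_linear(y, design, sub["sire"])
    overall_p = fit.joint_p(list(dummies.columns))

    weights = []
    for d, lab in zip(keep, labels):
        focal = {f"dip[{l}]": float(l == lab) for l in labels[1:]}
        weights.append(_emm_weights(design, focal))
    emm, se = [], []
    for c in weights:
        est, s, _ = fit.contrast(c)
        emm.append(est)
        se.append(s)
    k = len(keep)
    m = k * (k - 1) // 2
    adj = np.full((k, k), np.nan)
    significant: set[tuple[int, int]] = set()
    for i, j in itertools.combinations(range(k), 2):
        _, _, p = fit.contrast(weights[i] - weights[j])
        p_adj = min(1.0, p * m)
        adj[i, j] = adj[j, i] = p_adj
        if p_adj < spec.alpha:
            significant.add((i, j))
    letters = letter_display(k, significant)
    return DiplotypeResult(
        trait=trait, diplotypes=tuple(keep),
        n=tuple(int(counts[d]) for d in keep),
        emm=tuple(emm), se=tuple(se), letters=tuple(letters),
        overall_p=overall_p,
        pairwise_p=pd.DataFrame(adj, index=labels, columns=labels),
        notes=fit.notes)


# ---------------------------------------------------------------------------
# Structural-term selection


@dataclass
class StructureSelection:
    chosen: Optional[str]
    f_values: dict[str, float]
    p_values: dict[str, float]
    none_significant: bool


#: fixed priority for exact F ties
_STRUCTURE_PRIORITY = ("birth_rank", "birth_weight", "rearing_rank")


def select_structure_term(df: pd.DataFrame, trait: str,
                          model: Optional[TraitModel] = None
                          ) -> StructureSelection:
    """Choose among birth rank (factor), birth weight (covariate) and
    rearing rank (factor) by which has the larger F statistic when added
    alone to the trait's mandatory terms.  Ties follow a fixed priority;
    degenerate candidates (single level, zero variance, already mandatory)
    are skipped."""
    model = model or TRAIT_MODELS[trait]
    sub = _trait_subset(df, trait, model)
    fvals: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for cand in _STRUCTURE_PRIORITY:
        if cand in model.factors or cand in model.covariates:
            continue
        is_factor = cand in FACTOR_COLUMNS
        s = sub[sub[cand].notna()]
        if is_factor:
            if s[cand].nunique() < 2:
                continue
            focal_cols = pd.get_dummies(s[cand], prefix=cand, drop_first=True
                                        ).astype(float)
        else:
            if float(s[cand].astype(float).var()) == 0.0:
                continue
            focal_cols = s[[cand]].astype(float)
        try:
            design = _build_design(s, model.factors, model.covariates,
                                   focal_cols)
        except NotEstimableError:
            continue
        res = sm.OLS(s[trait].astype(float), design.matrix).fit()
        names = list(focal_cols.columns)
        A = np.zeros((len(names), design.matrix.shape[1]))
        for r_i, nm in enumerate(names):
            A[r_i, design.matrix.columns.get_loc(nm)] = 1.0
        ftest = res.f_test(A)
        fvals[cand] = float(ftest.fvalue)
        pvals[cand] = float(ftest.pvalue)
    if not fvals:
        return StructureSelection(None, fvals, pvals, True)
    best_f = max(fvals.values())
    chosen = next(c for c in _STRUCTURE_PRIORITY
                  if c in fvals and fvals[c] == best_f)
    return StructureSelection(chosen, fvals, pvals,
                              all(p >= 0.05 for p in pvals.values()))
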