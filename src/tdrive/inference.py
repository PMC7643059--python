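"""Estimation stages of the polyandry/drive analysis.

* polyandry rate among multi-pup litters, with a Wilson score interval;
* per-male sperm-competition intensity and lifetime reproductive success;
* overdispersed (quasi-Poisson) count regression of male reproductive
  success on competition intensity, t genotype and number of reproductive
  events, with qAIC model selection over all two-way-interaction submodels;
* drive-parameter estimators (drive strength d, sperm competitiveness c)
  from litter/pedigree tables;
* the female selection gradient of relative fitness on polyandry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hmean
from statsmodels.stats.proportion import proportion_confint

from .drive import WW, WT
from .mating import MisclassSpec, PolyandryCorrection, behavioural_from_genetic, mean_single_sire_prob

__all__ = [
    "PolyandryEstimate",
    "ParamEstimate",
    "MaleFitnessModel",
    "MaleFitnessResults",
    "SelectionGradientResult",
    "FitError",
    "estimate_polyandry",
    "competition_intensity",
    "fit_male_fitness",
    "estimate_drive_strength",
    "estimate_competitiveness",
    "female_summaries",
    "selection_gradient",
    "estimate_behavioural_polyandry",
]

logger = logging.getLogger("tdrive")


class FitError(RuntimeError):
    """Raised when a regression design is singular or degenerate."""


# ---------------------------------------------------------------------------
# polyandry rate


@dataclass(frozen=True)
class PolyandryEstimate:
    n: int
    k_multisire: int
    rate: float
    ci_low: float
    ci_high: float
    ci_method: str = "wilson"


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def estimate_polyandry(litters: pd.DataFrame) -> PolyandryEstimate:
    """Genetic polyandry rate: the proportion of litters (realised size >= 2)
    sired by more than one male, with a 95% Wilson score interval.

    Size-one litters are excluded internally — they cannot reveal multiple
    sires.
    """
    by_litter = litters.groupby("litter_id").agg(
        size=("pup_id", "size"), n_sires=("sire_id", "nunique")
    )
    eligible = by_litter[by_litter["size"] >= 2]
    n, k = len(eligible), int((eligible["n_sires"] >= 2).sum())
    logger.info(
        "estimate_polyandry: %d litters in, %d eligible (size>=2), %d multisire",
        len(by_litter), n, k,
    )
    if n == 0:
        raise ValueError("no litters of size >= 2; polyandry rate undefined")
    lo, hi = _wilson(k, n)
    return PolyandryEstimate(n=n, k_multisire=k, rate=k / n, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# per-male competition exposure


def competition_intensity(litters: pd.DataFrame, pedigree: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-male lifetime fitness and sperm-competition exposure.

    For every male with at least one pup: total offspring sired, number of
    litters with >= 1 pup sired, and the arithmetic and harmonic-style mean
    number of co-siring rivals per such litter (a co-sire count of a litter
    is its number of distinct sires minus one).  The harmonic summary is
    computed as hmean(1 + co-sires) − 1 so that uncontested litters do not
    annihilate the mean.

    Males with zero offspring never appear — an entirely unobserved male
    leaves no trace in paternity data.
    """
    n_sires = litters.groupby("litter_id")["sire_id"].nunique().rename("n_sires")
    df = litters.join(n_sires, on="litter_id")
    per_sire_litter = (
        df.groupby(["sire_id", "litter_id"])
        .agg(n_pups=("pup_id", "size"), n_sires=("n_sires", "first"))
        .reset_index()
    )
    per_sire_litter["co_sires"] = per_sire_litter["n_sires"] - 1

    rows = []
    for male, grp in per_sire_litter.groupby("sire_id"):
        co = grp["co_sires"].to_numpy(dtype=float)
        rows.append(
            {
                "male_id": male,
                "n_offspring": int(grp["n_pups"].sum()),
                "n_litters": int(len(grp)),
                "mean_competitors": float(co.mean()),
                "harmonic_competitors": float(hmean(co + 1.0) - 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["male_id", "n_offspring", "n_litters", "mean_competitors", "harmonic_competitors"])
    if pedigree is not None:
        geno = pedigree.set_index("id")["genotype"]
        out.insert(1, "genotype", out["male_id"].map(geno))
    return out


# ---------------------------------------------------------------------------
# male-fitness quasi-Poisson GLM


_MAIN_TERMS = ("genotype_WT", "competitors", "n_litters")
_INTERACTIONS = {
    ("genotype_WT", "competitors"): "genotype_WT:competitors",
    ("genotype_WT", "n_litters"): "genotype_WT:n_litters",
    ("competitors", "n_litters"): "competitors:n_litters",
}


def _design(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            X[t] = data[a] * data[b]
        else:
            X[t] = data[t]
    return X


def _candidate_term_sets() -> list[tuple[str, ...]]:
    """All submodels of the three main effects and their two-way
    interactions, respecting marginality (an interaction requires both of
    its main effects)."""
    sets: list[tuple[str, ...]] = []
    for r in range(len(_MAIN_TERMS) + 1):
        for mains in combinations(_MAIN_TERMS, r):
            admissible = [v for k, v in _INTERACTIONS.items() if set(k) <= set(mains)]
            for ri in range(len(admissible) + 1):
                for inters in combinations(admissible, ri):
                    sets.append(mains + inters)
    return sets


@dataclass
class MaleFitnessResults:
    """Fitted quasi-Poisson regression of male reproductive success.

    ``params``/``bse``/``pvalues`` are indexed by term name
    (``genotype_WT`` is the +/t contrast against the +/+ baseline,
    ``competitors`` the competition slope for +/+ males,
    ``genotype_WT:competitors`` the difference in competition slopes).
    ``deviance_fractions`` gives the sequential share of deviance explained
    by competition, genotype and their interaction once the number of
    litters is accounted for.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    dispersion: float
    selected_terms: tuple[str, ...]
    deviance_fractions: dict[str, float]
    selection_table: pd.DataFrame
    n_males: int
    _fit: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Male reproductive success — quasi-Poisson GLM (log link)",
            f"n males: {self.n_males}    dispersion (Pearson): {self.dispersion:.3f}",
            f"selected model (qAIC): success ~ {' + '.join(self.selected_terms) or '1'}",
            "",
            f"{'term':<28}{'coef':>10}{'SE':>10}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<28}{self.params[name]:>10.3f}{self.bse[name]:>10.3f}{self.pvalues[name]:>10.4f}"
            )
        lines.append("")
        lines.append(
            "deviance explained after n_litters: "
            + ", ".join(f"{k} {100 * v:.1f}%" for k, v in self.deviance_fractions.items())
        )
        return "\n".join(lines)


class MaleFitnessModel:
    """Quasi-Poisson model of male lifetime reproductive success.

    Built from the per-male table of :func:`competition_intensity` (must
    carry a ``genotype`` column).  ``fit`` selects among all
    two-way-interaction submodels by qAIC (quasi-likelihood information
    criterion, with the dispersion of the largest model), or fits the full
    model directly with ``select=False``.
    """

    def __init__(self, males: pd.DataFrame):
        if len(males) < 10:
            raise FitError(f"need at least 10 males, got {len(males)}")
        if "genotype" not in males.columns or males["genotype"].isna().any():
            raise FitError("male genotypes are required (merge from the pedigree)")
        if males["genotype"].nunique() < 2:
            raise FitError("need both +/+ and +/t males to estimate a genotype effect")
        data = pd.DataFrame(
            {
                "success": males["n_offspring"].to_numpy(dtype=float),
                "genotype_WT": (males["genotype"] == WT).to_numpy(dtype=float),
                "competitors": males["mean_competitors"].to_numpy(dtype=float),
                "n_litters": males["n_litters"].to_numpy(dtype=float),
            }
        )
        degenerate = [t for t in _MAIN_TERMS if data[t].nunique() <= 1]
        if degenerate:
            raise FitError(
                "degenerate (constant) covariates make the design singular: " + ", ".join(degenerate)
            )
        self.data = data

    def _glm(self, terms: tuple[str, ...], scale=None):
        X = _design(self.data, terms)
        model = sm.GLM(self.data["success"], X, family=sm.families.Poisson())
        return model.fit(scale=scale)

    def fit(self, select: bool = True) -> MaleFitnessResults:
        full_terms = _MAIN_TERMS + tuple(_INTERACTIONS.values())
        full = self._glm(full_terms)
        dispersion = float(full.pearson_chi2 / full.df_resid)

        rows = []
        for terms in _candidate_term_sets():
            res = self._glm(terms)
            k = len(terms) + 1  # + intercept
            qaic = float(res.deviance / dispersion + 2 * (k + 1))
            rows.append({"terms": " + ".join(terms) or "1", "_terms": terms, "df": k, "qAIC": qaic})
        table = pd.DataFrame(rows).sort_values("qAIC").reset_index(drop=True)

        selected = tuple(table.loc[0, "_terms"]) if select else full_terms
        res = self._glm(selected, scale="X2")

        # sequential deviance, competition/genotype/interaction entered after
        # the number of reproductive events
        seq = [
            ("n_litters",),
            ("n_litters", "competitors"),
            ("n_litters", "competitors", "genotype_WT"),
            ("n_litters", "competitors", "genotype_WT", "genotype_WT:competitors"),
        ]
        dev = [self._glm(t).deviance for t in seq]
        base = dev[0]
        fractions = {
            "competition": float((dev[0] - dev[1]) / base),
            "genotype": float((dev[1] - dev[2]) / base),
            "interaction": float((dev[2] - dev[3]) / base),
        }
        return MaleFitnessResults(
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            dispersion=float(res.scale),
            selected_terms=selected,
            deviance_fractions=fractions,
            selection_table=table.drop(columns="_terms"),
            n_males=len(self.data),
            _fit=res,
        )


def fit_male_fitness(males: pd.DataFrame, select: bool = True) -> MaleFitnessResults:
    """Fit the male reproductive-success regression; see
    :class:`MaleFitnessModel`."""
    return MaleFitnessModel(males).fit(select=select)


# ---------------------------------------------------------------------------
# drive-parameter estimators


@dataclass(frozen=True)
class ParamEstimate:
    """A binomial proportion estimate with its Wilson 95% interval."""

    estimate: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    conditional: bool = False
    ci_method: str = "wilson"


def _sire_genotypes(litters: pd.DataFrame, pedigree: pd.DataFrame) -> pd.Series:
    geno = pedigree.set_index("id")["genotype"]
    out = litters["sire_id"].map(geno)
    if out.isna().any():
        missing = litters.loc[out.isna(), "sire_id"].unique()[:5]
        raise ValueError(f"sires absent from pedigree: {list(missing)} ...")
    return out


def estimate_drive_strength(litters: pd.DataFrame, pedigree: pd.DataFrame) -> ParamEstimate:
    """Drive strength d: the proportion of +/t pups among offspring of +/t
    sires mated to +/+ dams in single-sire litters.

    Mixed-paternity litters are excluded (paternity shares would confound
    transmission) and so are +/t dams (maternal transmission and t/t loss
    would bias the proportion).
    """
    df = litters.copy()
    df["sire_genotype"] = _sire_genotypes(df, pedigree)
    n_sires = df.groupby("litter_id")["sire_id"].nunique()
    df["n_sires"] = df["litter_id"].map(n_sires)
    eligible = df[(df["n_sires"] == 1) & (df["mother_genotype"] == WW) & (df["sire_genotype"] == WT)]
    n = len(eligible)
    logger.info("estimate_drive_strength: %d eligible pups of %d", n, len(df))
    if n == 0:
        raise ValueError("no pups from +/t sire x +/+ dam single-sire litters; d inestimable")
    k = int((eligible["pup_genotype"] == WT).sum())
    lo, hi = _wilson(k, n)
    return ParamEstimate(estimate=k / n, ci_low=lo, ci_high=hi, k=k, n=n)


def estimate_competitiveness(
    litters: pd.DataFrame,
    matings: pd.DataFrame | None = None,
    pedigree: pd.DataFrame | None = None,
) -> ParamEstimate:
    """Sperm competitiveness c: the pooled paternity share of the +/t male
    in litters contested by exactly one +/t and one +/+ male.

    With full mating records (``matings``) every mixed two-mate litter
    counts, including those where one male achieved no paternity.  With
    paternity data alone the estimate is restricted to litters where both
    males sired >= 1 pup and is flagged ``conditional`` — it overstates c
    because all-or-nothing outcomes are invisible.

    Both modes use +/+ dams only, so that differential in-utero loss of t/t
    conceptions cannot distort the share.
    """
    mothers = litters.groupby("litter_id")["mother_genotype"].first()
    pups_per_litter = litters.groupby("litter_id")

    if matings is not None:
        m = matings[(matings["n_mates"] == 2)].copy()
        mixed = m[
            (m[["mate1_genotype", "mate2_genotype"]].apply(set, axis=1) == {WT, WW})
            & (m["litter_id"].map(mothers) == WW)
        ]
        if mixed.empty:
            raise ValueError("no mixed-genotype two-mate litters with +/+ dams; c inestimable")
        k = n = 0
        for _, row in mixed.iterrows():
            wt_male = row["mate1_id"] if row["mate1_genotype"] == WT else row["mate2_id"]
            pups = pups_per_litter.get_group(row["litter_id"])
            n += len(pups)
            k += int((pups["sire_id"] == wt_male).sum())
        lo, hi = _wilson(k, n)
        return ParamEstimate(estimate=k / n, ci_low=lo, ci_high=hi, k=k, n=n, conditional=False)

    if pedigree is None:
        raise ValueError("provide mating records or a pedigree with sire genotypes")
    df = litters.copy()
    df["sire_genotype"] = _sire_genotypes(df, pedigree)
    k = n = 0
    n_litters = 0
    for litter_id, grp in df.groupby("litter_id"):
        sires = grp.drop_duplicates("sire_id")
        if len(sires) != 2 or set(sires["sire_genotype"]) != {WT, WW}:
            continue
        if mothers[litter_id] != WW:
            continue
        n += len(grp)
        k += int((grp["sire_genotype"] == WT).sum())
        n_litters += 1
    logger.info("estimate_competitiveness (conditional): %d two-sire mixed litters", n_litters)
    if n == 0:
        raise ValueError("no two-sire mixed-genotype litters with +/+ dams; c inestimable")
    lo, hi = _wilson(k, n)
    return ParamEstimate(estimate=k / n, ci_low=lo, ci_high=hi, k=k, n=n, conditional=True)


# ---------------------------------------------------------------------------
# female selection gradient


def female_summaries(litters: pd.DataFrame) -> pd.DataFrame:
    """Per-female table: genotype, genetic polyandry proportion (among her
    litters of size >= 2) and total offspring.  Females with no eligible
    litter are dropped."""
    by_litter = litters.groupby("litter_id").agg(
        mother_id=("mother_id", "first"),
        genotype=("mother_genotype", "first"),
        size=("pup_id", "size"),
        n_sires=("sire_id", "nunique"),
    )
    offspring = litters.groupby("mother_id")["pup_id"].size()
    eligible = by_litter[by_litter["size"] >= 2]
    rows = []
    for mother, grp in eligible.groupby("mother_id"):
        rows.append(
            {
                "female_id": mother,
                "genotype": grp["genotype"].iloc[0],
                "polyandry": float((grp["n_sires"] >= 2).mean()),
                "n_eligible_litters": int(len(grp)),
                "mean_litter_size": float(grp["size"].mean()),
                "n_offspring": int(offspring[mother]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["female_id", "genotype", "polyandry", "n_eligible_litters", "mean_litter_size", "n_offspring"],
    )


@dataclass
class SelectionGradientResult:
    """Selection gradients of relative fitness on per-female polyandry."""

    gradient: float
    se: float
    pvalue: float
    per_genotype: dict[str, tuple[float, float]]
    contrast: float | None
    contrast_se: float | None
    contrast_pvalue: float | None
    n_females: int

    def summary(self) -> str:
        lines = [
            "Selection gradient of relative fitness on genetic polyandry",
            f"n females: {self.n_females}",
            f"pooled gradient: {self.gradient:.4f} (SE {self.se:.4f}, p {self.pvalue:.3f})",
        ]
        for g, (b, se) in self.per_genotype.items():
            lines.append(f"  {g}: {b:.4f} (SE {se:.4f})")
        if self.contrast is not None:
            lines.append(
                f"genotype x polyandry contrast: {self.contrast:.4f} "
                f"(SE {self.contrast_se:.4f}, p {self.contrast_pvalue:.3f})"
            )
        return "\n".join(lines)


def selection_gradient(females: pd.DataFrame) -> SelectionGradientResult:
    """Regress relative fitness (offspring / mean offspring) on the
    per-female genetic polyandry proportion, pooled and per maternal
    genotype, with the genotype x polyandry contrast when both genotypes
    are present.

    When the table carries a ``mean_litter_size`` column (as produced by
    :func:`female_summaries`) it enters as a covariate.  This is essential:
    multiple paternity is detected more readily in large litters, and large
    litters also mean high fitness, so the raw genetic-polyandry/fitness
    regression is confounded by detection.  Conditioning on litter size
    isolates the selection signal, the same reason the polyandry analysis
    itself must adjust for litter size.
    """
    if len(females) < 10:
        raise FitError(f"need at least 10 females, got {len(females)}")
    if females["polyandry"].nunique() <= 1:
        raise FitError("all polyandry values identical; gradient undefined")
    adjust = "mean_litter_size" in females.columns

    def _covs(df: pd.DataFrame) -> dict[str, pd.Series]:
        return {"mean_litter_size": df["mean_litter_size"]} if adjust else {}

    w = females["n_offspring"] / females["n_offspring"].mean()
    X = pd.DataFrame({"intercept": 1.0, "polyandry": females["polyandry"], **_covs(females)})
    pooled = sm.OLS(w, X).fit()

    per_genotype: dict[str, tuple[float, float]] = {}
    for g, grp in females.groupby("genotype"):
        if len(grp) >= 3 and grp["polyandry"].nunique() > 1:
            wg = grp["n_offspring"] / females["n_offspring"].mean()
            Xg = pd.DataFrame({"intercept": 1.0, "polyandry": grp["polyandry"], **_covs(grp)})
            fg = sm.OLS(wg, Xg).fit()
            per_genotype[g] = (float(fg.params["polyandry"]), float(fg.bse["polyandry"]))

    contrast = contrast_se = contrast_p = None
    if females["genotype"].nunique() == 2:
        gwt = (females["genotype"] == WT).astype(float)
        Xi = pd.DataFrame(
            {
                "intercept": 1.0,
                "polyandry": females["polyandry"],
                "genotype_WT": gwt,
                "genotype_WT:polyandry": gwt * females["polyandry"],
                **_covs(females),
            }
        )
        try:
            fi = sm.OLS(w, Xi).fit()
            contrast = float(fi.params["genotype_WT:polyandry"])
            contrast_se = float(fi.bse["genotype_WT:polyandry"])
            contrast_p = float(fi.pvalues["genotype_WT:polyandry"])
        except Exception:  # singular interaction design: leave contrast empty
            pass

    return SelectionGradientResult(
        gradient=float(pooled.params["polyandry"]),
        se=float(pooled.bse["polyandry"]),
        pvalue=float(pooled.pvalues["polyandry"]),
        per_genotype=per_genotype,
        contrast=contrast,
        contrast_se=contrast_se,
        contrast_pvalue=contrast_p,
        n_females=len(females),
    )


# ---------------------------------------------------------------------------
# behavioural-polyandry correction on data


def estimate_behavioural_polyandry(
    litters: pd.DataFrame, c: float, wt_freq: float | Mapping[int, float]
) -> tuple[PolyandryEstimate, PolyandryCorrection]:
    """Estimate the genetic polyandry rate and convert it to a behavioural
    rate using the misclassification model.

    The litter-size distribution is taken from the data (litters of size
    >= 2).  ``wt_freq`` is the adult male +/t frequency — either a single
    pooled value or a mapping cohort -> frequency; in the latter case the
    single-sire probability is averaged over cohorts, each with its own
    litter-size distribution, weighted by eligible litters per cohort.
    Cohort-resolved frequencies matter when the carrier frequency drifts
    over the study period, since the sire-pair genotype mixture is
    frequency-dependent.
    """
    est = estimate_polyandry(litters)
    by_litter = litters.groupby("litter_id").agg(size=("pup_id", "size"), cohort=("cohort", "first"))
    eligible = by_litter[by_litter["size"] >= 2]

    def _mbar(subset: pd.DataFrame, y: float) -> float:
        dist = subset["size"].value_counts(normalize=True).to_dict()
        spec = MisclassSpec(
            litter_size_dist={int(k): float(v) for k, v in dist.items()}, wt_freq=y, c=c
        )
        return mean_single_sire_prob(spec)

    if isinstance(wt_freq, Mapping):
        mbar = 0.0
        for cohort, grp in eligible.groupby("cohort"):
            if cohort not in wt_freq:
                raise ValueError(f"no +/t frequency supplied for cohort {cohort}")
            mbar += (len(grp) / len(eligible)) * _mbar(grp, wt_freq[cohort])
    else:
        mbar = _mbar(eligible, float(wt_freq))
    return est, behavioural_from_genetic(est.rate, mbar)
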