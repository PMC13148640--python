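"""Quadrupedal-versus-bipedal stance inference.

Four complementary lines of evidence, as used for small fossil
archosauriforms:

* allometric body-mass prediction from combined humeral + femoral minimum
  shaft circumferences (the published quadruped scaling equation);
* repeated linear-discriminant-analysis (LDA) classification of the focal
  taxon against a labelled morphometric dataset (body mass, dimensionless
  COM, forelimb and hindlimb lengths), run as a battery of tests over
  predictor subsets and training subsamples;
* a log-log regression of humeral on femoral circumference with
  class-cloud (convex-hull) placement of the focal taxon;
* the static-bipedalism criterion: the whole-body COM must lie less than
  one femur length cranial to the hips for the knee to be positioned under
  the COM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

# Quadruped stylopodial allometry: log10(mass in g) = a * log10(Ch + Cf in mm) + b
CAMPIONE_EVANS_SLOPE = 2.749
CAMPIONE_EVANS_INTERCEPT = -1.104


def campione_evans_mass(humeral_circumference_mm: float,
                        femoral_circumference_mm: float) -> float:
    """Body mass (kg) from humeral + femoral minimum shaft circumferences
    (mm) under the published quadruped scaling equation."""
    if humeral_circumference_mm <= 0 or femoral_circumference_mm <= 0:
        raise ValueError("circumferences must be positive")
    log_mass_g = (CAMPIONE_EVANS_SLOPE
                  * np.log10(humeral_circumference_mm + femoral_circumference_mm)
                  + CAMPIONE_EVANS_INTERCEPT)
    return float(10 ** log_mass_g / 1000.0)


# ---------------------------------------------------------------------------
# LDA stance battery
# ---------------------------------------------------------------------------

@dataclass
class LDATestSpec:
    """One test of the battery: which predictor columns to use and,
    optionally, a training subsample fraction (seeded)."""

    name: str
    predictors: tuple
    subsample: float = 1.0


@dataclass
class LDAVerdict:
    per_test: pd.DataFrame  # test, predictors, p_quadrupedal, call, ok
    n_quadrupedal: int
    n_tests: int

    def summary(self) -> str:
        return f"{self.n_quadrupedal} of {self.n_tests} tests predict quadrupedalism"


def default_test_battery(predictors=("body_mass", "com_dimensionless",
                                     "forelimb_length", "hindlimb_length"),
                         n_subsample_tests: int = 7) -> list:
    """A 22-test battery for synthetic work: every non-empty subset of the
    four predictors (15 tests) plus seeded 75% training subsamples on all
    predictors (7 tests). Non-canonical: the published battery's definitions
    are external inputs and can be passed explicitly instead."""
    specs = []
    for k in range(1, len(predictors) + 1):
        for combo in combinations(predictors, k):
            specs.append(LDATestSpec(f"subset_{'_'.join(combo)}", combo))
    for i in range(n_subsample_tests):
        specs.append(LDATestSpec(f"subsample75_{i + 1}", tuple(predictors), 0.75))
    return specs


def lda_stance_tests(dataset: pd.DataFrame, focal: str, test_specs: list = None,
                     seed: int = 0, priors=None) -> LDAVerdict:
    """Run the LDA battery: for each test, fit a two-class linear
    discriminant (pooled covariance) on the labelled rows and report the
    posterior probability that the focal taxon is quadrupedal.

    ``dataset`` needs a ``taxon`` column, a ``stance`` column with values
    in {"biped", "quadruped", "unknown"}, and numeric predictor columns.
    A test whose pooled covariance is singular is marked failed (ok=False),
    not silently dropped. Fully reproducible given ``seed``.
    """
    if test_specs is None:
        test_specs = default_test_battery()
    focal_row = dataset[dataset["taxon"] == focal]
    if len(focal_row) != 1:
        raise ValueError(f"focal taxon {focal!r} must appear exactly once")
    labelled = dataset[dataset["stance"].isin(["biped", "quadruped"])]
    rng = np.random.default_rng(seed)
    rows = []
    n_quad = 0
    for spec in test_specs:
        train = labelled
        if spec.subsample < 1.0:
            idx = rng.choice(len(labelled), size=max(
                2, int(round(spec.subsample * len(labelled)))), replace=False)
            train = labelled.iloc[np.sort(idx)]
        X = train[list(spec.predictors)].to_numpy(float)
        y = (train["stance"] == "quadruped").to_numpy()
        row = {"test": spec.name, "predictors": "+".join(spec.predictors),
               "p_quadrupedal": np.nan, "call": "failed", "ok": False}
        if len(np.unique(y)) == 2:
            try:
                lda = LinearDiscriminantAnalysis(priors=priors)
                lda.fit(X, y)
                xq = focal_row[list(spec.predictors)].to_numpy(float)
                p = float(lda.predict_proba(xq)[0][list(lda.classes_).index(True)])
                row.update(p_quadrupedal=p,
                           call="quadruped" if p > 0.5 else "biped", ok=True)
                if p > 0.5:
                    n_quad += 1
            except (np.linalg.LinAlgError, ValueError, IndexError):
                pass  # singular pooled covariance et al.: marked failed below
        rows.append(row)
    return LDAVerdict(pd.DataFrame(rows), n_quad, len(test_specs))


# ---------------------------------------------------------------------------
# Circumference regression and morphospace placement
# ---------------------------------------------------------------------------

@dataclass
class CircumferenceRegression:
    slope: float
    intercept: float
    r_squared: float
    focal_in_hull: dict  # class label -> bool
    hulls: dict = field(repr=False, default_factory=dict)


def circumference_regression(table: pd.DataFrame, focal: str = None) -> CircumferenceRegression:
    """OLS of log10 humeral on log10 femoral circumference, plus per-class
    convex hulls and (optionally) whether the focal taxon falls inside each
    labelled class's 2D cloud.

    ``table`` columns: taxon, log_humeral, log_femoral, stance.
    """
    x = table["log_femoral"].to_numpy(float)
    y = table["log_humeral"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: femoral circumferences all equal")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    hulls, in_hull = {}, {}
    focal_pt = None
    if focal is not None:
        fr = table[table["taxon"] == focal]
        if len(fr) != 1:
            raise ValueError(f"focal taxon {focal!r} must appear exactly once")
        focal_pt = fr[["log_femoral", "log_humeral"]].to_numpy(float)[0]
    for label, grp in table[table["stance"].isin(["biped", "quadruped"])].groupby("stance"):
        pts = grp[["log_femoral", "log_humeral"]].to_numpy(float)
        if len(pts) >= 3 and np.linalg.matrix_rank(pts - pts.mean(0)) == 2:
            hull = ConvexHull(pts)
            hulls[label] = pts[hull.vertices]
            if focal_pt is not None:
                in_hull[label] = bool(
                    Delaunay(pts).find_simplex(focal_pt[None, :])[0] >= 0)
    return CircumferenceRegression(float(slope), float(intercept), float(r2),
                                   in_hull, hulls)


# ---------------------------------------------------------------------------
# Static bipedalism criterion
# ---------------------------------------------------------------------------

@dataclass
class StaticBipedalismVerdict:
    ratio: float  # COM cranial offset / femur length
    percent: float
    verdict: str
    marginal: bool


def static_bipedalism_check(com_offset_m: float, femur_length_m: float) -> StaticBipedalismVerdict:
    """Static criterion for bipedal competence: the COM must sit less than
    one femur length cranial to the hips (ratio < 1), else the knee cannot
    be placed cranial to the COM and knee extensors lose their antigravity
    role. Ratios in [0.6, 1.0) are flagged as pushing the limits."""
    if femur_length_m <= 0:
        raise ValueError("femur_length must be positive")
    ratio = com_offset_m / femur_length_m
    if ratio >= 1.0:
        verdict, marginal = "fails static criterion", False
    elif ratio >= 0.6:
        verdict, marginal = "passes, pushing the limits", True
    else:
        verdict, marginal = "passes static criterion", False
    return StaticBipedalismVerdict(float(ratio), float(100 * ratio), verdict, marginal)
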