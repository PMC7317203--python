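"""Per-band linear mixed-model screening of derivative spectra.

For each of the 31 binned derivative bands and each measurement period, a
linear mixed model is fitted with fertilizer regime (3-level factor) and
infestation group (2-level factor) as additive fixed effects and the growing
time series as a random intercept.  At baseline the infestation factor is
the *assigned* group (insects not yet released), so baseline contrasts test
pre-infestation group differences.  With only two series the random
intercept is frequently degenerate; when the mixed fit fails or returns
non-finite p-values the model falls back to ordinary least squares with
series as a fixed blocking factor and the fit is flagged ``converged=False``.

Significance is assessed per band at ``alpha`` without multiple-testing
correction; an optional Benjamini-Hochberg flag is provided but off by
default.  A band is a *reliable* infestation indicator when it responds
significantly to infestation in all three periods while never responding to
fertilizer regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .preprocess import derivative_columns
from .synth_scene import PERIODS

DEFAULT_ALPHA = 0.05

_FORMULA_MIXED = (
    "y ~ C(fertilizer, levels=['low', 'medium', 'high']) + C(grp)"
)
_FORMULA_BLOCK = _FORMULA_MIXED + " + C(series)"


@dataclass(frozen=True)
class BandFit:
    """Result of one (band, period) mixed-model fit."""

    band_nm: float
    period: str
    p_fertilizer: float
    p_infestation: float
    converged: bool


@dataclass
class ScreenMap:
    """All 31 bands x 3 periods fits for one crop, with significance flags."""

    crop: str
    fits: list[BandFit]
    alpha: float = DEFAULT_ALPHA
    bh_correct: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "crop": self.crop,
                "band_nm": [f.band_nm for f in self.fits],
                "period": [f.period for f in self.fits],
                "p_fert": [f.p_fertilizer for f in self.fits],
                "p_inf": [f.p_infestation for f in self.fits],
                "converged": [f.converged for f in self.fits],
            }
        )
        if self.bh_correct:
            df["sig_fert"] = multipletests(df["p_fert"], self.alpha, "fdr_bh")[0]
            df["sig_inf"] = multipletests(df["p_inf"], self.alpha, "fdr_bh")[0]
        else:
            df["sig_fert"] = df["p_fert"] < self.alpha
            df["sig_inf"] = df["p_inf"] < self.alpha
        return df


def _wald_p(result, term_prefix: str) -> float:
    names = [n for n in result.model.exog_names if n.startswith(term_prefix)]
    if not names:
        raise ValueError(f"no design terms match {term_prefix!r}")
    constraint = ", ".join(f"{n} = 0" for n in names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # F form of the Wald test: small-sample calibration at ~100
        # observations per period, where the chi-square form is liberal
        try:
            test = result.wald_test(constraint, scalar=True, use_f=True)
        except (TypeError, ValueError):
            test = result.wald_test(constraint, scalar=True)
    return float(test.pvalue)


def fit_band(
    frame: pd.DataFrame,
    band_col: str,
    period: str,
) -> BandFit:
    """Fit one band x period mixed model and return its factor p-values.

    p-values are Wald chi-square tests on the factor terms of the mixed fit
    (F tests for the fixed-block fallback).  Requires at least two levels of
    each fixed factor in the period's data.
    """
    sub = frame[frame["period"] == period]
    data = pd.DataFrame(
        {
            "y": sub[band_col].to_numpy(dtype=float),
            "fertilizer": sub["fertilizer"].to_numpy(),
            "grp": sub["assigned"].to_numpy(dtype=bool),
            "series": sub["series"].to_numpy(),
        }
    )
    for factor, needed in (("fertilizer", 3), ("grp", 2)):
        levels = data[factor].nunique()
        if levels < needed:
            missing = set(
                ["low", "medium", "high"] if factor == "fertilizer" else [True, False]
            ) - set(data[factor])
            raise ValueError(
                f"rank-deficient design in period {period!r}: "
                f"factor {factor!r} missing level(s) {sorted(map(str, missing))}"
            )
    band_nm = float(band_col[1:])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(_FORMULA_MIXED, data, groups=data["series"])
            res = model.fit(reml=True)
        p_fert = _wald_p(res, "C(fertilizer")
        p_inf = _wald_p(res, "C(grp)")
        if np.isfinite(p_fert) and np.isfinite(p_inf):
            return BandFit(band_nm, period, p_fert, p_inf, converged=True)
    except (Exception,):
        pass

    # fixed-block fallback: series as a fixed factor in OLS
    res = smf.ols(_FORMULA_BLOCK, data).fit()
    p_fert = _wald_p(res, "C(fertilizer")
    p_inf = _wald_p(res, "C(grp)")
    return BandFit(band_nm, period, p_fert, p_inf, converged=False)


def screen_all(
    deriv_frame: pd.DataFrame,
    crop: str = "",
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> ScreenMap:
    """Fit every (band, period) combination: 31 x 3 = 93 fits per crop."""
    bands = derivative_columns(deriv_frame)
    if not bands:
        raise ValueError("frame has no derivative band columns")
    fits = [
        fit_band(deriv_frame, col, period)
        for col in bands
        for period in PERIODS
    ]
    return ScreenMap(crop=crop, fits=fits, alpha=alpha, bh_correct=bh_correct)


def null_calibration(
    n_fits: int = 500,
    seed: int = 0,
    n_per_cell: int = 10,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Type-I-error simulation for :func:`fit_band`.

    Draws ``n_fits`` independent null data sets (pure Gaussian noise on a
    balanced two-series design with both fixed factors, no true effects),
    fits each, and returns the factor p-values.  The empirical rejection
    rate at any alpha estimates the test's size at that alpha.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA1]))
    rows = [
        {"series": s, "fertilizer": f, "assigned": a, "period": "early"}
        for s in (1, 2)
        for f in ("low", "medium", "high")
        for a in (False, True)
        for _ in range(n_per_cell)
    ]
    base = pd.DataFrame(rows)
    out = []
    for i in range(n_fits):
        data = base.copy()
        data["d700.00"] = rng.normal(0.0, noise_sd, size=len(base))
        fit = fit_band(data, "d700.00", "early")
        out.append(
            {"p_fert": fit.p_fertilizer, "p_inf": fit.p_infestation,
             "converged": fit.converged}
        )
    return pd.DataFrame(out)


def reliable_bands(screen: ScreenMap) -> list[float]:
    """Bands significant for infestation in every period and never for
    fertilizer — candidate single-band infestation indicators."""
    df = screen.to_frame()
    out = []
    for band, grp in df.groupby("band_nm"):
        if len(grp) == len(PERIODS) and grp["sig_inf"].all() and not grp["sig_fert"].any():
            out.append(float(band))
    return sorted(out)
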