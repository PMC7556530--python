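"""Turn raw birth records into the model-ready analysis table.

Steps, in the order a survey analyst applies them:

1. prior-death indicator from the full (unfiltered) birth history, so
   siblings outside the analysis window still inform it;
2. exposure-window filter — keep births occurring at least 5 and less than
   10 years before the survey, so every kept birth has full five-year
   exposure and recall error stays bounded;
3. within-survey wealth CDF transform at the household level (midpoint
   ranks), giving relative wealth on (0, 1) comparable across surveys;
4. wealth quintile assignment (quintile 1 = poorest).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "filter_births",
    "wealth_cdf_transform",
    "assign_quintiles",
    "prior_death_indicator",
    "build_analysis_table",
    "SurveyPreprocessor",
    "cmc_to_decimal_year",
]

REQUIRED_COLUMNS = [
    "birth_id",
    "survey_id",
    "cluster_id",
    "mother_id",
    "birth_order",
    "birth_date",
    "survey_date",
    "sex",
    "maternal_age_at_birth",
    "maternal_education",
    "wealth_score",
    "urban",
    "died_u5",
]

WINDOW_YEARS = (5.0, 10.0)  # [5, 10): full 5-year exposure, bounded recall

#: Expected mapping from DHS Births Recode variables to the input schema.
#: Documentation stub only — untested against real recode files, which are
#: access-restricted.  Dates arrive as century-month codes; convert with
#: :func:`cmc_to_decimal_year`.  ``died_u5`` derives from b5 (child alive)
#: and b7 (age at death in months): died_u5 = 1 iff b7 < 60.
DHS_BIRTHS_RECODE_MAPPING = {
    "survey_id": "v000+v007 (country code and survey year)",
    "cluster_id": "v001",
    "mother_id": "caseid",
    "birth_order": "bord",
    "birth_date": "b3 (CMC)",
    "survey_date": "v008 (CMC)",
    "sex": "b4",
    "maternal_age_at_birth": "(b3 - v011) / 12",
    "maternal_education": "v133",
    "wealth_score": "v191",
    "urban": "v025",
    "died_u5": "b5/b7 (died before 60 months)",
    "death_date": "b3 + b7 (CMC)",
}


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"birth records missing required column(s): {', '.join(missing)}")


def cmc_to_decimal_year(cmc) -> np.ndarray:
    """Convert DHS century-month codes (months since Jan 1900) to decimal years."""
    cmc = np.asarray(cmc, dtype=float)
    return 1900.0 + (cmc - 1.0) / 12.0


def filter_births(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep births whose age at survey lies in the [5, 10)-year window.

    Returns the kept records and a count of exclusions by reason.  Records
    with a missing survey date are rejected with a logged warning.
    """
    _check_columns(records)
    missing_survey = records["survey_date"].isna()
    if missing_survey.any():
        logger.warning("dropping %d record(s) with missing survey_date", int(missing_survey.sum()))
    age_at_survey = records["survey_date"] - records["birth_date"]
    too_recent = (~missing_survey) & (age_at_survey < WINDOW_YEARS[0])
    too_old = (~missing_survey) & (age_at_survey >= WINDOW_YEARS[1])
    kept = records.loc[~(missing_survey | too_recent | too_old)].copy()
    exclusions = {
        "missing_survey_date": int(missing_survey.sum()),
        "under_five_years_before_survey": int(too_recent.sum()),
        "ten_or_more_years_before_survey": int(too_old.sum()),
    }
    logger.info("window filter kept %d of %d births (%s)", len(kept), len(records), exclusions)
    return kept, exclusions


def wealth_cdf_transform(scores, survey_ids=None) -> np.ndarray:
    """Within-survey empirical CDF of wealth scores, midpoint-rank convention.

    Each score maps to (rank - 0.5) / n within its survey, with tied scores
    sharing their mean rank, so the output lies strictly inside (0, 1) and
    is invariant under any strictly increasing rescaling of the raw scores.
    """
    scores = np.asarray(scores, dtype=float)
    if survey_ids is None:
        survey_ids = np.zeros(scores.shape[0], dtype=int)
    survey_ids = np.asarray(survey_ids)
    out = np.empty_like(scores)
    for sid in pd.unique(survey_ids):
        mask = survey_ids == sid
        s = scores[mask]
        if s.size < 2:
            raise ValueError(f"survey {sid!r} needs at least 2 households for the wealth CDF transform")
        if np.all(s == s[0]):
            logger.warning("survey %r: all wealth scores identical; assigning CDF 0.5", sid)
            out[mask] = 0.5
            continue
        out[mask] = (rankdata(s, method="average") - 0.5) / s.size
    return out


def assign_quintiles(wealth_cdf) -> np.ndarray:
    """Quintile of relative wealth, 1 (poorest) to 5 (richest)."""
    cdf = np.asarray(wealth_cdf, dtype=float)
    if np.any((cdf <= 0) | (cdf >= 1)):
        raise ValueError("wealth_cdf values must lie strictly inside (0, 1)")
    return np.clip(np.ceil(5.0 * cdf).astype(int), 1, 5)


def prior_death_indicator(records: pd.DataFrame) -> np.ndarray:
    """Whether the mother had already lost an earlier child at this birth.

    1 iff some lower-order sibling died before age five AND its death
    occurred strictly before the index birth; first births are always 0.
    Only earlier births inform the indicator, never later ones.  When a
    sibling died but its death date is missing, the death is counted only
    if it must have happened before the index birth (sibling born more than
    five years earlier); those imputations are counted and logged.
    """
    _check_columns(records)
    df = records[["survey_id", "mother_id", "birth_order", "birth_date", "died_u5"]].copy()
    if "death_date" in records.columns:
        df["death_date"] = pd.to_numeric(records["death_date"], errors="coerce")
    else:
        df["death_date"] = np.nan

    died = df["died_u5"].to_numpy() == 1
    missing = died & ~np.isfinite(df["death_date"].to_numpy(dtype=float))
    if missing.any():
        logger.warning(
            "prior_death: %d died sibling(s) had no death date; timing imputed conservatively",
            int(missing.sum()),
        )
    # effective death moment for the strictly-before comparison: the known
    # death date when present; when absent, the end of the sibling's 5-year
    # risk window (the latest moment the death could have happened)
    eff = np.where(
        died,
        np.where(np.isfinite(df["death_date"].to_numpy(dtype=float)), df["death_date"], df["birth_date"] + 5.0),
        np.inf,
    )
    df["_eff"] = eff
    df["_pos"] = np.arange(len(df))
    df = df.sort_values(["survey_id", "mother_id", "birth_order"], kind="stable")
    keys = [df["survey_id"], df["mother_id"]]
    earliest = df.groupby(keys, sort=False)["_eff"].cummin()
    earliest_prior = earliest.groupby(keys, sort=False).shift(1)
    indicator = (earliest_prior < df["birth_date"]).fillna(False).to_numpy().astype(int)
    out = np.zeros(len(df), dtype=int)
    out[df["_pos"].to_numpy()] = indicator
    return out


def build_analysis_table(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full preprocessing pipeline: indicator, window filter, wealth transform.

    The prior-death indicator is computed on the complete birth history
    before filtering, so elder siblings outside the window still count.
    Wealth is ranked over the unique households (mothers) present in the
    filtered analysis population, one score per household.  Records with a
    pre-assigned ``wealth_quintile`` column keep it; otherwise quintiles are
    cut from the wealth CDF at 0.2, 0.4, 0.6, 0.8.

    Returns the analysis table and the exclusion counts from the filter.
    """
    _check_columns(records)
    records = records.copy()
    records["prior_death"] = prior_death_indicator(records)
    kept, exclusions = filter_births(records)

    n_missing = kept[REQUIRED_COLUMNS].isna().any(axis=1)
    if n_missing.any():
        logger.warning("dropping %d record(s) with missing model covariates", int(n_missing.sum()))
        exclusions["missing_covariates"] = int(n_missing.sum())
        kept = kept.loc[~n_missing]
    else:
        exclusions["missing_covariates"] = 0

    households = kept.drop_duplicates(subset=["survey_id", "mother_id"])[
        ["survey_id", "mother_id", "wealth_score"]
    ].copy()
    households["wealth_cdf"] = wealth_cdf_transform(
        households["wealth_score"].to_numpy(), households["survey_id"].to_numpy()
    )
    kept = kept.merge(households[["survey_id", "mother_id", "wealth_cdf"]], on=["survey_id", "mother_id"], how="left")
    if "wealth_quintile" not in kept.columns:
        kept["wealth_quintile"] = assign_quintiles(kept["wealth_cdf"].to_numpy())
    return kept.reset_index(drop=True), exclusions


class SurveyPreprocessor(BaseEstimator, TransformerMixin):
    """Scikit-learn-style transformer wrapping :func:`build_analysis_table`.

    The transform is stateless across surveys (all statistics are
    within-survey ranks), so ``fit`` only validates the schema.  After
    ``transform``, ``exclusions_`` records how many births each filter rule
    removed.
    """

    def fit(self, X: pd.DataFrame, y=None):
        _check_columns(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        table, exclusions = build_analysis_table(X)
        self.exclusions_ = exclusions
        return table
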