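"""Reading camera-trap records and site covariates into model-ready structures.

A survey consists of cameras deployed at fixed sites for a number of days,
divided into replicate sampling occasions (here: weekly blocks counted from
each site's own deployment start). Detection records — one row per independent
photo event — are collapsed to a binary site × occasion detection history, the
``y_i / n_i`` of the binomial detection model. Covariates are standardized to
mean 0 / SD 1 (sample SD, n−1 denominator) and screened for pairwise
collinearity before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("camcat")

RECORD_COLUMNS = ["site_id", "species", "timestamp", "count"]
COVARIATE_COLUMNS = [
    "site_id", "x", "y", "canopycover", "dist_water", "dist_road",
    "dist_settlement", "human", "livestock", "predators",
]

#: default window (minutes) within which photo events of one species at one
#: site are treated as a single detection.
INDEPENDENCE_MINUTES = 30


@dataclass(frozen=True)
class SurveyDesign:
    """Camera-trap survey layout: sites, deployment length, occasion length."""

    n_sites: int
    deployment_days: int = 21
    occasion_days: int = 7

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.deployment_days <= 0 or self.occasion_days <= 0:
            raise ValueError("deployment_days and occasion_days must be positive")
        if self.occasions_per_site < 1:
            raise ValueError("occasion_days longer than the deployment")

    @property
    def occasions_per_site(self) -> int:
        """Complete occasions per site; trailing partial occasions are dropped."""
        return self.deployment_days // self.occasion_days

    @property
    def trap_days(self) -> int:
        """Total survey effort in camera-days (sites × deployment days)."""
        return self.n_sites * self.deployment_days


@dataclass
class DetectionHistory:
    """Binary site × occasion detections for one species.

    ``y[i, j]`` is 1 iff the species was detected at site ``i`` during
    occasion ``j``; ``n[i]`` is the number of occasions surveyed at site
    ``i``. ``y_total[i] = Σ_j y[i, j]`` is the binomial count the occupancy
    model consumes.
    """

    sites: list
    y: np.ndarray
    n: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.y.ndim != 2 or self.y.shape[0] != len(self.sites):
            raise ValueError("y must be (n_sites, n_occasions)")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y entries must be 0/1")
        if (self.y_total > self.n).any():
            raise ValueError("y_total exceeds the number of occasions surveyed")

    @property
    def y_total(self) -> np.ndarray:
        return self.y.sum(axis=1)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def naive_occupancy(self) -> float:
        """Fraction of sites with at least one detection."""
        return float((self.y_total > 0).mean())


@dataclass
class StandardizedDesign:
    """Covariates scaled to mean 0 / SD 1 with the transform retained."""

    frame: pd.DataFrame
    mean: pd.Series
    sd: pd.Series

    @property
    def covariates(self) -> list[str]:
        return list(self.frame.columns)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Project new rows onto the stored standardization."""
        return (table[self.covariates] - self.mean) / self.sd

    def inverse(self, frame: pd.DataFrame | None = None) -> pd.DataFrame:
        """Map standardized values back to the original scale."""
        if frame is None:
            frame = self.frame
        return frame * self.sd + self.mean


@dataclass
class CorrelationReport:
    """Pairs of covariates whose |Pearson r| exceeds the screening threshold."""

    pairs: list[tuple[str, str, float]]
    threshold: float
    correlation: pd.DataFrame = field(repr=False, default=None)

    @property
    def passed(self) -> bool:
        return not self.pairs


def read_records(path) -> pd.DataFrame:
    """Read a detection-record CSV (site_id, species, timestamp, count)."""
    df = pd.read_csv(path, dtype={"site_id": str, "species": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record file missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if (df["count"] < 1).any():
        raise ValueError("record counts must be >= 1")
    return df[RECORD_COLUMNS]


def read_covariates(path) -> pd.DataFrame:
    """Read the site covariate CSV; extra columns (e.g. strata flags) are kept."""
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"covariate file missing columns: {sorted(missing)}")
    if df["site_id"].duplicated().any():
        raise ValueError("covariate table must have one row per site")
    if df.isna().any().any():
        raise ValueError("covariate table contains missing values")
    if ((df["canopycover"] < 0) | (df["canopycover"] > 100)).any():
        raise ValueError("canopycover must lie in [0, 100]")
    return df


def collapse_independent_events(
    records: pd.DataFrame, minutes: float = INDEPENDENCE_MINUTES
) -> pd.DataFrame:
    """Merge photo events of one species at one site closer than ``minutes``.

    Standard camera-trap independence rule: within a site/species stream, an
    event starts a new detection only if it falls at least ``minutes`` after
    the previously kept event.
    """
    if records.empty:
        return records.copy()
    out = []
    gap = pd.Timedelta(minutes=minutes)
    for _, grp in records.sort_values("timestamp").groupby(
        ["site_id", "species"], sort=False
    ):
        last = None
        for row in grp.itertuples(index=True):
            if last is None or row.timestamp - last >= gap:
                out.append(row.Index)
                last = row.timestamp
    kept = records.loc[sorted(out)].reset_index(drop=True)
    logger.debug("independence collapse: %d -> %d events", len(records), len(kept))
    return kept


def build_detection_history(
    records: pd.DataFrame,
    design: SurveyDesign,
    species: str,
    sites: Sequence,
    deployment_start: Mapping | pd.Timestamp | str,
) -> DetectionHistory:
    """Collapse detection records into a binary site × occasion history.

    Occasion windows are consecutive ``occasion_days`` blocks counted from
    each site's deployment start (site-relative, not calendar weeks).
    Records at unknown sites raise; records outside the deployment window are
    excluded with a logged warning.
    """
    sites = list(sites)
    if len(sites) != design.n_sites:
        raise ValueError(
            f"site list has {len(sites)} entries but design declares {design.n_sites}"
        )
    site_index = {s: i for i, s in enumerate(sites)}
    if isinstance(deployment_start, (pd.Timestamp, str)):
        start_of = {s: pd.Timestamp(deployment_start) for s in sites}
    else:
        start_of = {s: pd.Timestamp(t) for s, t in deployment_start.items()}
        if set(sites) - set(start_of):
            raise ValueError("deployment_start missing sites")

    J = design.occasions_per_site
    y = np.zeros((design.n_sites, J), dtype=np.int8)
    dropped = 0
    sub = records[records["species"] == species]
    unknown = set(sub["site_id"]) - set(site_index)
    if unknown:
        raise ValueError(f"records reference unknown sites: {sorted(unknown)}")
    for row in sub.itertuples():
        start = start_of[row.site_id]
        days = (row.timestamp - start).total_seconds() / 86400.0
        occ = int(np.floor(days / design.occasion_days))
        if days < 0 or occ >= J:
            dropped += 1
            continue
        y[site_index[row.site_id], occ] = 1
    if dropped:
        logger.warning(
            "%d %s record(s) outside the deployment window were excluded",
            dropped, species,
        )
    n = np.full(design.n_sites, J, dtype=np.int64)
    return DetectionHistory(sites=sites, y=y, n=n, species=species)


def other_species_presence(
    records: pd.DataFrame, other_species: str, sites: Sequence
) -> pd.Series:
    """0/1 per-site presence of the *other* cat, used as an occupancy covariate."""
    detected = set(records.loc[records["species"] == other_species, "site_id"])
    return pd.Series(
        [1 if s in detected else 0 for s in sites], index=list(sites), name="othercat"
    )


def standardize(
    table: pd.DataFrame, covariates: Iterable[str]
) -> StandardizedDesign:
    """Scale named covariates to mean 0 / SD 1 (sample SD, n−1 denominator)."""
    covariates = list(covariates)
    missing = set(covariates) - set(table.columns)
    if missing:
        raise ValueError(f"unknown covariates: {sorted(missing)}")
    sub = table[covariates].astype(float)
    mean = sub.mean()
    sd = sub.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant covariate(s) cannot be standardized: {constant}")
    frame = (sub - mean) / sd
    if "site_id" in table.columns:
        frame.index = pd.Index(table["site_id"], name="site_id")
    return StandardizedDesign(frame=frame, mean=mean, sd=sd)


def screen_collinearity(
    design: StandardizedDesign | pd.DataFrame, threshold: float = 0.7
) -> CorrelationReport:
    """List covariate pairs with |Pearson r| above ``threshold``."""
    frame = design.frame if isinstance(design, StandardizedDesign) else design
    if frame.shape[1] < 2 or frame.shape[0] < 3:
        raise ValueError("collinearity screen needs >= 2 covariates and >= 3 sites")
    corr = frame.corr(method="pearson")
    cols = list(frame.columns)
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) > threshold:
                pairs.append((a, b, r))
    return CorrelationReport(pairs=pairs, threshold=threshold, correlation=corr)
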