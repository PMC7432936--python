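"""Quality control and reference-site temporal adjustment.

Field blanks give a limit of detection (LOD = mean + 3 SD of the blanks, the
usual convention when no protocol-specific formula applies); field duplicates
give a precision check (squared Pearson correlation with the primary
samplers). Records flagged stolen or outlier are excluded; records below the
LOD are kept but flagged (exclusion is configurable).

Intermittent 2-week site means are then adjusted to annual (or seasonal)
averages with the reference-site difference method: each site period is
corrected by the deviation of its co-temporal reference period from the
reference long-term mean,

    adjusted = mean_i [ site_i - (ref_i - ref_scope_mean) ].

The correction is exact whenever a site's series runs parallel to the
reference series (differs by a constant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .synthetic_city import ReferenceSeries


@dataclass
class QAResult:
    pollutant: str
    lod: float
    duplicate_r2: float  # NaN when undefined (no duplicates / zero variance)
    n_blanks: int
    n_duplicates: int
    excluded: dict = field(default_factory=dict)  # reason -> count

    def to_dict(self) -> dict:
        return {
            "pollutant": self.pollutant,
            "lod_ugm3": self.lod,
            "duplicate_r2": None if np.isnan(self.duplicate_r2) else self.duplicate_r2,
            "n_blanks": self.n_blanks,
            "n_duplicates": self.n_duplicates,
            "excluded": dict(self.excluded),
        }


@dataclass(frozen=True)
class AdjustedConcentration:
    site_id: str
    pollutant: str
    scope: str  # 'annual' | season name
    value: float  # ug/m3
    n_periods: int


def limit_of_detection(blanks) -> float:
    """LOD from field blanks: mean + 3 x sample SD (needs >= 2 blanks)."""
    b = np.asarray(blanks, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 field blanks to estimate an LOD")
    return float(b.mean() + 3.0 * b.std(ddof=1))


def duplicate_agreement(primary, duplicate) -> float:
    """Squared Pearson correlation of paired primary/duplicate measurements.

    Undefined (NaN, with a warning) when either series has zero variance.
    """
    x = np.asarray(primary, dtype=float)
    y = np.asarray(duplicate, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired duplicate measurements")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("duplicate agreement undefined: zero variance", stacklevel=2)
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def apply_qa(
    records: pd.DataFrame,
    *,
    exclude_below_lod: bool = False,
) -> tuple[pd.DataFrame, dict[str, QAResult]]:
    """Screen a campaign record table.

    Returns the cleaned analysis records (blanks/duplicates removed,
    stolen/outlier records excluded, below-LOD records flagged and optionally
    excluded) and one :class:`QAResult` per pollutant.
    """
    results: dict[str, QAResult] = {}
    keep_parts = []
    for pollutant, grp in records.groupby("pollutant", sort=False):
        blanks = grp.loc[grp["flag"] == "blank", "value_ugm3"].to_numpy()
        dups = grp[grp["flag"] == "duplicate"]
        lod = limit_of_detection(blanks) if blanks.size >= 2 else float("nan")
        primaries = grp[grp["flag"] == ""]
        dup_r2 = float("nan")
        if len(dups) >= 3:
            merged = dups.merge(
                primaries[["site_id", "period_id", "value_ugm3"]],
                on=["site_id", "period_id"],
                suffixes=("_dup", "_pri"),
            )
            if len(merged) >= 3:
                dup_r2 = duplicate_agreement(
                    merged["value_ugm3_pri"], merged["value_ugm3_dup"]
                )
        excluded = {
            "stolen": int((grp["flag"] == "stolen").sum()),
            "outlier": int((grp["flag"] == "outlier").sum()),
        }
        analysis = grp[grp["flag"] == ""].copy()
        if not np.isnan(lod):
            below = analysis["value_ugm3"] < lod
            analysis.loc[below, "flag"] = "below-LOD"
            if exclude_below_lod:
                excluded["below-LOD"] = int(below.sum())
                analysis = analysis[~below]
            else:
                excluded["below-LOD"] = 0
        keep_parts.append(analysis)
        results[pollutant] = QAResult(
            pollutant, lod, dup_r2, int(blanks.size), int(len(dups)), excluded
        )
    cleaned = pd.concat(keep_parts, ignore_index=True) if keep_parts else records.iloc[0:0]
    return cleaned, results


def _map_to_reference_period(start, end, reference: ReferenceSeries) -> int:
    """Reference period with maximal calendar overlap; ties go to the earlier."""
    best_pid, best_overlap = None, -1
    for pid, rs, re_ in zip(reference.period_ids, reference.starts, reference.ends):
        overlap = (min(end, re_) - max(start, rs)).days
        if overlap > best_overlap:
            best_pid, best_overlap = int(pid), overlap
    if best_pid is None or best_overlap <= 0:
        raise AlignmentError(f"no co-temporal reference period for [{start}, {end})")
    return best_pid


def adjust_to_scope(
    site_records: pd.DataFrame,
    reference: ReferenceSeries,
    scope: str = "annual",
) -> AdjustedConcentration:
    """Adjust one site's period means for one pollutant to a scope average.

    ``site_records`` holds the retained (unflagged) records of a single site
    and pollutant with columns start/end/value_ugm3 (and season, used to
    restrict seasonal scopes). For the annual scope the formula subtracts the
    co-temporal reference deviation from the reference annual mean; seasonal
    scopes use the reference season mean instead and only that season's
    records.
    """
    recs = site_records
    if scope != "annual":
        recs = recs[recs["season"] == scope]
    if len(recs) == 0:
        raise AlignmentError(f"no records in scope {scope!r}")
    ref_scope = reference.scope_mean(scope)
    adj = []
    for _, row in recs.iterrows():
        pid = row.get("period_id")
        if pid is None or (isinstance(pid, float) and np.isnan(pid)):
            pid = _map_to_reference_period(row["start"], row["end"], reference)
        else:
            pid = int(pid)
            if pid not in set(int(q) for q in reference.period_ids):
                pid = _map_to_reference_period(row["start"], row["end"], reference)
        adj.append(row["value_ugm3"] - (reference.value_for(pid) - ref_scope))
    sid = recs["site_id"].iloc[0] if "site_id" in recs else ""
    pol = recs["pollutant"].iloc[0] if "pollutant" in recs else reference.pollutant
    return AdjustedConcentration(sid, pol, scope, float(np.mean(adj)), len(adj))


def adjust_all(
    records: pd.DataFrame,
    references: dict[str, ReferenceSeries],
    scopes=("annual", "summer", "winter", "spring"),
) -> pd.DataFrame:
    """Adjusted means for every site x pollutant x scope with data.

    Input records should already be QA-screened. Returns a long DataFrame
    with columns site_id, region, site_type, pollutant, scope, value_ugm3,
    n_periods. Sites with no record in a seasonal scope are skipped.
    """
    rows = []
    usable = records[records["flag"].isin(["", "below-LOD"])]
    for (sid, pollutant), grp in usable.groupby(["site_id", "pollutant"], sort=False):
        ref = references.get(pollutant)
        if ref is None:
            continue
        for scope in scopes:
            try:
                a = adjust_to_scope(grp, ref, scope)
            except AlignmentError:
                continue
            rows.append(
                (
                    sid,
                    grp["region"].iloc[0] if "region" in grp else "",
                    grp["site_type"].iloc[0] if "site_type" in grp else "",
                    pollutant,
                    scope,
                    a.value,
                    a.n_periods,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "region", "site_type", "pollutant", "scope", "value_ugm3", "n_periods"],
    )
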