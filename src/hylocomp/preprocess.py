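"""Variable transformations, response coding and the collinearity screen.

Transformations follow the study conventions: continuous variables spanning
an order of magnitude or more are log10-transformed, human-footprint
percentages are converted to proportions and arcsine(-square-root)
transformed, latitude enters as its absolute value, and the categorical
mating system is binary-coded (polygyny = 1, monogamy = 0, solitary = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformLog",
    "validate_population_table",
    "transform_variables",
    "code_mating_system",
    "collinearity_screen",
    "LOG_RULE_RATIO",
    "LOG_CANDIDATES",
    "PREDICTOR_COLUMNS",
    "RESPONSE_COLUMNS",
]

#: "varied by an order of magnitude" operationalised as max/min >= 10
LOG_RULE_RATIO = 10.0

#: continuous columns eligible for the log10 rule (coordinates and
#: already-bounded indices are excluded; temperature in degC may be <= 0
#: and is never a log candidate)
LOG_CANDIDATES = (
    "HR",
    "GS",
    "body_mass",
    "group_density",
    "altitude",
    "annual_precipitation",
    "precipitation_seasonality",
    "reserve_area",
)

PREDICTOR_COLUMNS = (
    "body_mass",
    "group_density",
    "latitude",
    "longitude",
    "altitude",
    "annual_mean_temperature",
    "annual_precipitation",
    "precipitation_seasonality",
    "NDVI",
    "GHF",
    "reserve_area",
)

RESPONSE_COLUMNS = ("HR", "GS", "MS")

_MS_CODES = {"polygyny": 1, "monogamy": 0, "solitary": 0}


@dataclass
class TransformLog:
    """Per-variable record of which rule was applied."""

    records: list[dict]

    def rule_for(self, variable: str) -> str | None:
        for rec in self.records:
            if rec["variable"] == variable:
                return rec["rule"]
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def validate_population_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a raw population table."""
    required = {"population_id", "species"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    if table["population_id"].duplicated().any():
        dups = table.loc[table["population_id"].duplicated(), "population_id"]
        raise ValueError(f"duplicate population_id values: {sorted(set(dups))}")
    if "HR" in table and (table["HR"] <= 0).any():
        raise ValueError("HR must be strictly positive")
    if "GS" in table and (table["GS"] < 1).any():
        raise ValueError("GS must be >= 1")
    if "GHF" in table:
        ghf = table["GHF"].to_numpy(float)
        if np.any((ghf < 0) | (ghf > 100)):
            raise ValueError("GHF must lie in [0, 100]")
    if "NDVI" in table:
        ndvi = table["NDVI"].to_numpy(float)
        if np.any((ndvi < -1) | (ndvi > 1)):
            raise ValueError("NDVI must lie in [-1, 1]")


def transform_variables(
    table: pd.DataFrame, arcsine_variant: str = "asin-sqrt"
) -> tuple[pd.DataFrame, TransformLog]:
    """Apply the modelling-scale transformations, returning table + log.

    Rules, applied in place on the named columns:

    * ``GHF`` (percent) -> proportion -> arcsine(sqrt(p)) (or plain
      arcsine with ``arcsine_variant='asin'``).  Skipped when the column is
      already on the arcsine scale (all values <= pi/2), which makes the
      operation idempotent.
    * ``latitude`` -> absolute value.
    * any column in :data:`LOG_CANDIDATES` whose max/min ratio is >=
      :data:`LOG_RULE_RATIO` -> log10.  Requires strictly positive values.
    """
    if arcsine_variant not in ("asin-sqrt", "asin"):
        raise ValueError("arcsine_variant must be 'asin-sqrt' or 'asin'")
    out = table.copy()
    # idempotence marker: columns transformed in a previous in-memory pass
    done = set(out.attrs.get("transformed_variables", ()))
    records: list[dict] = []

    if "GHF" in out.columns:
        ghf = out["GHF"].to_numpy(float)
        # the data-scale guard (values beyond pi/2 must be percentages)
        # backs up the marker when the table was serialised in between
        if "GHF" not in done and np.nanmax(ghf) > np.pi / 2:
            p = ghf / 100.0
            out["GHF"] = np.arcsin(np.sqrt(p)) if arcsine_variant == "asin-sqrt" else np.arcsin(p)
            records.append(
                {"variable": "GHF", "rule": "arcsine-proportion",
                 "parameters": arcsine_variant}
            )
            done.add("GHF")
        else:
            records.append({"variable": "GHF", "rule": "none", "parameters": ""})

    if "latitude" in out.columns:
        lat = out["latitude"].to_numpy(float)
        if np.any(lat < 0):
            out["latitude"] = np.abs(lat)
            records.append({"variable": "latitude", "rule": "absolute-value", "parameters": ""})
        else:
            records.append({"variable": "latitude", "rule": "none", "parameters": ""})

    for name in LOG_CANDIDATES:
        if name not in out.columns:
            continue
        if name in done:
            records.append({"variable": name, "rule": "none", "parameters": ""})
            continue
        col = out[name].to_numpy(float)
        lo, hi = np.nanmin(col), np.nanmax(col)
        if lo <= 0:
            row = int(np.nanargmin(col))
            raise ValueError(
                f"log-candidate variable {name!r} has non-positive value "
                f"{lo} at row {row}"
            )
        if hi / lo >= LOG_RULE_RATIO:
            out[name] = np.log10(col)
            records.append(
                {"variable": name, "rule": "log10",
                 "parameters": f"max/min={hi / lo:.3g}"}
            )
            done.add(name)
        else:
            records.append({"variable": name, "rule": "none", "parameters": ""})

    out.attrs["transformed_variables"] = sorted(done)
    return out, TransformLog(records)


def code_mating_system(table: pd.DataFrame) -> pd.DataFrame:
    """Add the binary ``MS01`` column (polygyny = 1; monogamy/solitary = 0)."""
    out = table.copy()
    if "MS" not in out.columns:
        raise ValueError("table has no MS column")
    unknown = sorted(set(out["MS"]) - set(_MS_CODES))
    if unknown:
        raise ValueError(f"unknown mating-system categories: {unknown}")
    out["MS01"] = out["MS"].map(_MS_CODES).astype(int)
    return out


def _adjusted_r2(r2: float, n: int) -> float:
    # simple two-variable regression: one slope, one intercept
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def collinearity_screen(
    table: pd.DataFrame,
    predictors: list[str],
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation / adjusted R^2 screen among predictors.

    A pair is flagged when either |r| or the adjusted R^2 of the simple
    linear fit reaches ``threshold``.  Returns the per-pair report and the
    retained predictor list (all predictors when nothing is flagged; when a
    pair is flagged, the later-listed member is dropped).
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictors to screen")
    for name in predictors:
        col = table[name].to_numpy(float)
        if np.allclose(col, col[0]):
            raise ValueError(f"predictor {name!r} is constant; correlation undefined")
    rows = []
    dropped: set[str] = set()
    n = len(table)
    for i in range(len(predictors)):
        for j in range(i + 1, len(predictors)):
            a, b = predictors[i], predictors[j]
            r, _ = stats.pearsonr(table[a].to_numpy(float), table[b].to_numpy(float))
            adj = _adjusted_r2(r * r, n)
            flagged = bool(abs(r) >= threshold or adj >= threshold)
            rows.append(
                {"predictor_a": a, "predictor_b": b, "abs_r": abs(r),
                 "adjusted_r2": adj, "flagged": flagged}
            )
            if flagged and a not in dropped:
                dropped.add(b)
    report = pd.DataFrame(rows)
    retained = [p for p in predictors if p not in dropped]
    return report, retained
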