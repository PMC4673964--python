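"""File I/O, configuration and the scoring/equity pipeline.

All tabular input and output is comma-separated text with a mandatory
header. Record files carry one row per surveyed individual with the
columns

    income, occupation_rank, education_level, tenure, home_surface,
    price_quintile, rent, family_size, access_status

plus an optional ``price_per_m2`` column used only when owners lack a
precomputed ``price_quintile``. Cells belonging to the tenure branch not
in use are left empty. Currencies are unit-agnostic: every monetary
value is interpreted relative to the configured city poverty line (CPL)
or national minimum wage (NMW), and numbers use a "." decimal
separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
import yaml

from . import ses
from .access import ACCESS_SCORES, AccessStatus
from .concentration import (
    ConcentrationResult,
    GroupedDistribution,
    build_grouped_distribution,
    concentration_curve,
)
from .errors import SchemaError, ValidationError
from .ses import DEFAULT_WEIGHTS, EconomicAnchors, SESWeights

logger = logging.getLogger(__name__)

__all__ = [
    "RECORD_COLUMNS",
    "PipelineConfig",
    "load_config",
    "read_records",
    "write_records",
    "run_score",
    "run_equity",
    "write_curve",
    "write_report",
]

RECORD_COLUMNS = (
    "income",
    "occupation_rank",
    "education_level",
    "tenure",
    "home_surface",
    "price_quintile",
    "rent",
    "family_size",
    "access_status",
)

SCORE_COLUMNS = (
    "income_score",
    "occupation_score",
    "education_score",
    "home_score",
    "family_score",
    "composite",
    "ses_class",
    "access_score",
)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the records themselves."""

    anchors: EconomicAnchors
    weights: SESWeights = field(default_factory=lambda: DEFAULT_WEIGHTS)
    grouping: str = "classes"  # "classes" or "quantiles"
    n_quantiles: int = 5
    aggregation: str = "score"  # "score" (access-score mass) or "count"
    price_quintile_breaks: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.grouping not in ("classes", "quantiles"):
            raise ValidationError(
                f"grouping must be 'classes' or 'quantiles', got {self.grouping!r}"
            )
        if self.aggregation not in ("score", "count"):
            raise ValidationError(
                f"aggregation must be 'score' or 'count', got {self.aggregation!r}"
            )
        if self.price_quintile_breaks is not None:
            breaks = [float(b) for b in self.price_quintile_breaks]
            if len(breaks) != 4 or sorted(breaks) != breaks:
                raise ValidationError(
                    "price_quintile_breaks must be 4 ascending numbers"
                )
            self.price_quintile_breaks = breaks


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Read a YAML pipeline configuration.

    Recognised keys: ``cpl``, ``nmw`` (required, positive), an optional
    ``weights`` block with income/occupation/education/home/family
    percentages, and optional ``grouping``, ``n_quantiles``,
    ``aggregation``, ``price_quintile_breaks``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "cpl" not in raw or "nmw" not in raw:
        raise SchemaError("config must supply both 'cpl' and 'nmw'")
    anchors = EconomicAnchors(cpl=float(raw["cpl"]), nmw=float(raw["nmw"]))
    weights = DEFAULT_WEIGHTS
    if "weights" in raw:
        w = raw["weights"]
        weights = SESWeights(
            income_w=float(w.get("income", 30)),
            occupation_w=float(w.get("occupation", 27)),
            education_w=float(w.get("education", 20)),
            home_w=float(w.get("home", 13)),
            family_w=float(w.get("family", 10)),
        )
    return PipelineConfig(
        anchors=anchors,
        weights=weights,
        grouping=raw.get("grouping", "classes"),
        n_quantiles=int(raw.get("n_quantiles", 5)),
        aggregation=raw.get("aggregation", "score"),
        price_quintile_breaks=raw.get("price_quintile_breaks"),
    )


def read_records(path: Union[str, Path, TextIO]) -> pd.DataFrame:
    """Read a record file, checking that every required column is present."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"input is missing required column(s): {', '.join(missing)}")
    return df


def write_records(df: pd.DataFrame, path: Union[str, Path, TextIO]) -> None:
    df.to_csv(path, index=False)


def _resolve_owner_quintiles(
    df: pd.DataFrame, owner: pd.Series, config: PipelineConfig
) -> tuple[pd.Series, pd.Series]:
    """Fill missing owner price quintiles; return (quintile, unresolved mask).

    Resolution order: explicit price_quintile; config breakpoints applied
    to price_per_m2; empirical owner quintiles of price_per_m2 (logged);
    otherwise the row is unresolved.
    """
    quintile = pd.to_numeric(df.get("price_quintile"), errors="coerce")
    needs = owner & quintile.isna()
    if not needs.any():
        return quintile, needs
    if "price_per_m2" in df.columns:
        price = pd.to_numeric(df["price_per_m2"], errors="coerce")
    else:
        price = pd.Series(np.nan, index=df.index)
    if config.price_quintile_breaks is not None:
        breaks = np.asarray(config.price_quintile_breaks, dtype=float)
        fillable = needs & price.notna()
        quintile.loc[fillable] = (
            np.searchsorted(breaks, price.loc[fillable].to_numpy(), side="left") + 1
        )
        return quintile, needs & ~fillable
    owner_prices = price[owner & price.notna()]
    if len(owner_prices) >= 5:
        breaks = np.quantile(owner_prices.to_numpy(), [0.2, 0.4, 0.6, 0.8])
        logger.info(
            "price quintiles computed empirically from %d owner records "
            "(breaks: %s)", len(owner_prices), np.round(breaks, 3).tolist()
        )
        fillable = needs & price.notna()
        quintile.loc[fillable] = (
            np.searchsorted(breaks, price.loc[fillable].to_numpy(), side="left") + 1
        )
        return quintile, needs & ~fillable
    return quintile, needs


def run_score(
    records: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, list[str]]:
    """Score every record: per-indicator scores, composite, class, access.

    Returns the scored frame (valid rows only, original columns plus the
    eight score columns) and a list of line-numbered diagnostics for the
    rejected rows. Line numbers count the header as line 1.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"input is missing required column(s): {', '.join(missing)}")
    df = records.reset_index(drop=True).copy()
    n = len(df)
    bad: dict[int, str] = {}

    def flag(mask: pd.Series, message: str) -> None:
        for i in df.index[mask.fillna(False)]:
            bad.setdefault(int(i), message)

    income = pd.to_numeric(df["income"], errors="coerce")
    flag(income.isna() | (income < 0), "income must be a nonnegative number")

    occ = df["occupation_rank"].astype(str).str.strip().str.lower()
    occ_valid = occ.isin([r.value for r in ses.OccupationRank])
    flag(~occ_valid, "unknown occupation_rank (expected high/average/low)")

    edu = df["education_level"].astype(str).str.strip().str.lower()
    edu_valid = edu.isin([l.value for l in ses.EducationLevel])
    flag(~edu_valid, "unknown education_level")

    tenure = df["tenure"].astype(str).str.strip().str.lower()
    owner = tenure == ses.Tenure.OWNER.value
    tenant = tenure == ses.Tenure.TENANT.value
    flag(~(owner | tenant), "tenure must be 'owner' or 'tenant'")

    surface = pd.to_numeric(df["home_surface"], errors="coerce")
    flag(owner & (surface.isna() | (surface <= 0)), "owner rows need a positive home_surface")
    quintile, unresolved = _resolve_owner_quintiles(df, owner, config)
    flag(
        unresolved,
        "owner row lacks price_quintile and no breakpoints or price_per_m2 "
        "data are available to derive it",
    )
    flag(
        owner & quintile.notna() & ~quintile.isin([1, 2, 3, 4, 5]),
        "price_quintile must be an integer 1-5",
    )

    rent = pd.to_numeric(df["rent"], errors="coerce")
    flag(tenant & (rent.isna() | (rent < 0)), "tenant rows need a nonnegative rent")

    fs = pd.to_numeric(df["family_size"], errors="coerce")
    flag(fs.isna() | (fs < 1) | (fs != fs.round()), "family_size must be a positive integer")

    acc = df["access_status"].astype(str).str.strip().str.lower()
    label_scores = {s.value: float(ACCESS_SCORES[s]) for s in AccessStatus}
    access_score = acc.map(label_scores)
    row_numbers = pd.to_numeric(acc, errors="coerce")  # 1-based table row also accepted
    scores_by_row = np.array([float(ACCESS_SCORES[s]) for s in AccessStatus])
    num_ok = row_numbers.isin([1, 2, 3, 4, 5, 6, 7, 8, 9])
    access_score = access_score.where(
        access_score.notna() | ~num_ok,
        pd.Series(
            scores_by_row[np.clip(row_numbers.fillna(1).astype(int) - 1, 0, 8)],
            index=df.index,
        ),
    )
    flag(access_score.isna(), "unrecognized access_status (use a label or a row number 1-9)")

    ok = ~df.index.isin(list(bad))
    out = df.loc[ok].copy()
    w = config.weights
    a = config.anchors

    inc_score = np.searchsorted(
        np.array([0.5, 1, 2, 3, 4, 5]) * a.cpl, income.loc[ok].to_numpy(), side="left"
    ) + 1
    occ_score = occ.loc[ok].map({"high": 6, "average": 3, "low": 1}).to_numpy()
    edu_score = (
        edu.loc[ok]
        .map({"under_diploma": 1, "diploma_to_bachelor": 4, "master_and_above": 7})
        .to_numpy()
    )

    home_score = np.zeros(ok.sum(), dtype=int)
    own = owner.loc[ok].to_numpy()
    s = np.searchsorted([100, 200, 300, 400], surface.loc[ok].to_numpy(), side="left") + 1
    p = 2 * quintile.loc[ok].to_numpy(dtype=float, na_value=np.nan) - 1
    product = s * p
    ho_idx = np.searchsorted([5, 15, 29, 39, 45], product, side="left")
    ho_idx = np.clip(ho_idx, 0, 4)
    home_score[own] = np.array([4, 5, 7, 9, 10])[ho_idx[own]]
    r = rent.loc[ok].to_numpy() / a.nmw
    t_idx = np.searchsorted([1 / 3, 1.0, 2.0], r, side="right")
    t_idx = np.where(r > 5, 4, t_idx)
    home_score[~own] = np.array([1, 2, 3, 6, 8])[t_idx[~own]]

    fam = fs.loc[ok].to_numpy()
    fam_score = np.select([fam <= 2, fam == 3, fam == 4], [8, 5, 3], default=1)

    composite = (
        w.income_w * inc_score
        + w.occupation_w * occ_score
        + w.education_w * edu_score
        + w.home_w * home_score
        + w.family_w * fam_score
    )
    out["income_score"] = inc_score
    out["occupation_score"] = occ_score
    out["education_score"] = edu_score
    out["home_score"] = home_score
    out["family_score"] = fam_score
    out["composite"] = composite
    out["ses_class"] = [ses.classify_ses(c).value for c in composite]
    out["access_score"] = access_score.loc[ok].astype(int).to_numpy()

    errors = [
        f"line {i + 2}: {msg}" for i, msg in sorted(bad.items())
    ]  # +2: header is line 1, frame index is 0-based
    return out, errors


def _access_mass(scored: pd.DataFrame, aggregation: str) -> np.ndarray:
    """Per-individual access contribution under the chosen aggregation.

    "score" uses the 9-level access score itself (score mass); "count"
    uses binary availability — 1 unless the medicine was not available
    at all.
    """
    if aggregation == "score":
        return scored["access_score"].to_numpy(dtype=float)
    if aggregation == "count":
        if "access_status" in scored.columns:
            status = scored["access_status"].astype(str).str.strip().str.lower()
            return (status != AccessStatus.NOT_AVAILABLE.value).to_numpy(dtype=float)
        return (scored["access_score"].to_numpy(dtype=float) > ACCESS_SCORES[AccessStatus.NOT_AVAILABLE]).astype(float)
    raise ValidationError(f"unknown aggregation {aggregation!r}")


def run_equity(
    scored: pd.DataFrame, config: PipelineConfig
) -> tuple[GroupedDistribution, ConcentrationResult]:
    """Build the grouped distribution and concentration curve from scored rows."""
    for col in ("ses_class", "composite", "access_score"):
        if col not in scored.columns:
            raise SchemaError(f"scored input is missing required column: {col}")
    mass = _access_mass(scored, config.aggregation)
    if config.grouping == "classes":
        pairs = list(zip(scored["ses_class"], mass))
        dist = build_grouped_distribution(pairs, grouping="five_classes")
    else:
        pairs = list(zip(scored["composite"], mass))
        dist = build_grouped_distribution(
            pairs, grouping="custom_quantiles", n_quantiles=config.n_quantiles
        )
    logger.info(
        "equity groups: %s (population shares %s)",
        dist.groups,
        np.round(dist.pop_share, 4).tolist(),
    )
    return dist, concentration_curve(dist)


def write_curve(
    dist: GroupedDistribution,
    result: ConcentrationResult,
    path: Union[str, Path, TextIO],
    include_equity_line: bool = False,
) -> None:
    """Write curve points as CSV (group, P, L), origin row included.

    With ``include_equity_line`` an extra column repeats P as the
    45-degree reference, ready for plotting.
    """
    rows = [("origin", 0.0, 0.0)] + [
        (g, float(p), float(l)) for g, p, l in zip(dist.groups, dist.P, dist.L)
    ]
    curve = pd.DataFrame(rows, columns=["group", "P", "L"])
    if include_equity_line:
        curve["equity_line"] = curve["P"]
    curve.to_csv(path, index=False)


def write_report(
    dist: GroupedDistribution,
    result: ConcentrationResult,
    path: Union[str, Path],
    config: PipelineConfig,
) -> None:
    """Write a flat key=value summary of the equity computation."""
    lines = [
        f"concentration_index={result.index:.6f}",
        f"n_groups={dist.n_groups}",
        f"groups={','.join(dist.groups)}",
        f"grouping={config.grouping}",
        f"aggregation={config.aggregation}",
        f"pop_shares={','.join(f'{v:.6f}' for v in dist.pop_share)}",
        f"access_shares={','.join(f'{v:.6f}' for v in dist.access_mass / dist.access_mass.sum())}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
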