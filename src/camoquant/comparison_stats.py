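"""Paired response-ratio contrasts between backgrounds with bootstrap CIs.

The experimental question — does a pattern metric differ between
backgrounds? — is answered here with paired response ratios: for each
specimen measured under two conditions, the contrast A vs B is the ratio of
geometric means across specimens, with a 95% percentile interval from
bootstrap resampling of specimens.  Ratios of geometric means are the
natural effect size for strictly positive, log-scale metrics, and they are
what contrast tables in this literature report.

This is a deliberate simplification of a Gamma GLMM with per-individual
random effects: the mixed model is off-the-shelf machinery, while the
paired ratio-of-geometric-means is the quantity the contrasts express, and
a seed-controlled bootstrap keeps the estimator dependency-light and
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_scene import EXPERIMENTAL_BACKGROUNDS


@dataclass(frozen=True)
class RatioContrast:
    """One pairwise contrast: point ratio and 95% percentile interval."""

    condition_a: str
    condition_b: str
    ratio: float
    lower: float
    upper: float
    n: int
    metric: str | None = None
    species: str | None = None

    def __post_init__(self):
        if not (self.lower <= self.ratio <= self.upper):
            raise ValueError("interval must contain the point estimate")
        if min(self.ratio, self.lower, self.upper) <= 0:
            raise ValueError("ratios must be positive")

    @property
    def excludes_one(self) -> bool:
        """True when the 95% interval excludes a ratio of 1 (bold-equivalent)."""
        return self.lower > 1.0 or self.upper < 1.0

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "species": self.species,
            "contrast": f"{self.condition_a} - {self.condition_b}",
            "ratio": self.ratio,
            "lower": self.lower,
            "upper": self.upper,
            "n": self.n,
            "excludes_one": self.excludes_one,
        }


REQUIRED_COLUMNS = ("specimen", "condition", "metric", "value")


def validate_metric_table(tbl: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format metric table: columns, positivity, uniqueness."""
    for col in REQUIRED_COLUMNS:
        if col not in tbl.columns:
            raise ValueError(f"metric table lacks required column {col!r}")
    if (tbl["value"] <= 0).any():
        raise ValueError("metric values must be strictly positive")
    dup = tbl.duplicated(subset=["specimen", "condition", "metric"])
    if dup.any():
        raise ValueError("each specimen x condition must appear once per metric")
    return tbl


def response_ratio(
    tbl: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    metric: str | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    species: str | None = None,
) -> RatioContrast:
    """Paired response ratio A/B with a bootstrap percentile interval.

    Specimens present in both conditions are paired by id; unpaired
    specimens are dropped (count reported via the returned ``n``).  The
    point estimate is ``exp(mean(log a_i - log b_i))`` — the ratio of
    geometric means — and the interval is the 2.5/97.5 percentile of the
    same statistic over ``n_boot`` resamples of specimens with replacement.
    """
    tbl = validate_metric_table(tbl)
    sub = tbl
    if metric is not None:
        sub = sub[sub["metric"] == metric]
    if species is not None:
        sub = sub[sub["species"] == species]
    a = sub[sub["condition"] == cond_a].set_index("specimen")["value"]
    b = sub[sub["condition"] == cond_b].set_index("specimen")["value"]
    paired = a.index.intersection(b.index)
    n_dropped = len(a.index.union(b.index)) - len(paired)
    if n_dropped:
        import logging
        logging.getLogger("camoquant").warning(
            "response_ratio %s vs %s: dropped %d unpaired specimens",
            cond_a, cond_b, n_dropped,
        )
    if len(paired) < 3:
        raise ValueError(
            f"need >= 3 paired specimens for {cond_a} vs {cond_b}, have {len(paired)}"
        )
    log_ratios = np.log(a.loc[paired].to_numpy()) - np.log(b.loc[paired].to_numpy())
    point = float(np.exp(log_ratios.mean()))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(log_ratios), size=(n_boot, len(log_ratios)))
    boot = np.exp(log_ratios[idx].mean(axis=1))
    lower, upper = np.percentile(boot, [2.5, 97.5])
    lower = float(min(lower, point))
    upper = float(max(upper, point))
    return RatioContrast(
        condition_a=cond_a, condition_b=cond_b, ratio=point,
        lower=lower, upper=upper, n=len(paired),
        metric=metric, species=species,
    )


def contrast_table(
    tbl: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    first_backgrounds: dict | pd.Series | None = None,
) -> pd.DataFrame:
    """All pairwise background contrasts, plus acclimation-vs-first contrasts.

    Per species and metric, the three pairwise contrasts among the
    experimental backgrounds are computed.  When ``first_backgrounds`` maps
    specimens to the experimental background they encountered first (or the
    table carries a ``first_background`` column), the acclimation vs first
    experimental background contrast is added, pooled and split by first
    background type.  Missing conditions drop the affected contrast with a
    warning rather than failing the whole table.
    """
    import itertools
    import logging

    tbl = validate_metric_table(tbl)
    log = logging.getLogger("camoquant")
    if first_backgrounds is None and "first_background" in tbl.columns:
        fb = tbl.drop_duplicates("specimen").set_index("specimen")["first_background"]
        first_backgrounds = fb.to_dict()

    species_levels = (
        sorted(tbl["species"].dropna().unique()) if "species" in tbl.columns else [None]
    ) or [None]
    rows = []
    for metric in sorted(tbl["metric"].unique()):
        for sp in species_levels:
            for cond_a, cond_b in itertools.combinations(EXPERIMENTAL_BACKGROUNDS, 2):
                try:
                    rows.append(response_ratio(
                        tbl, cond_a, cond_b, metric=metric, species=sp,
                        n_boot=n_boot, seed=seed,
                    ).to_row())
                except ValueError as exc:
                    log.warning("contrast %s-%s (%s, %s) omitted: %s",
                                cond_a, cond_b, metric, sp, exc)
            if first_backgrounds is None:
                continue
            sub = tbl[tbl["metric"] == metric]
            if sp is not None:
                sub = sub[sub["species"] == sp]
            first = pd.Series(first_backgrounds)
            paired_first = sub[sub.apply(
                lambda r: r["condition"] == first.get(r["specimen"]), axis=1
            )].copy()
            paired_first["condition"] = "first_experimental"
            accl = sub[sub["condition"] == "acclimation"]
            for scope in ("pooled",) + EXPERIMENTAL_BACKGROUNDS:
                block = paired_first if scope == "pooled" else paired_first[
                    paired_first["specimen"].map(first) == scope
                ]
                merged = pd.concat([accl, block], ignore_index=True)
                try:
                    rc = response_ratio(
                        merged, "acclimation", "first_experimental",
                        metric=metric, species=sp, n_boot=n_boot, seed=seed,
                    )
                    row = rc.to_row()
                    row["contrast"] = (
                        "acclimation - first experimental"
                        + ("" if scope == "pooled" else f" ({scope})")
                    )
                    rows.append(row)
                except ValueError as exc:
                    log.warning("acclimation contrast (%s, %s, %s) omitted: %s",
                                metric, sp, scope, exc)
    return pd.DataFrame(rows)
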