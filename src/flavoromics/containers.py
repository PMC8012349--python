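"""Typed containers for panel ratings, chemical matrices and genotypes.

All containers wrap pandas objects and validate their invariants on
construction: rating scales are bounded, every sample carries exactly one
period label, compound identifiers are unique, and genotype dosages are
integral codes in {0, 1, 2} (missing allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Hedonic attributes scored on the bipolar [-100, +100] hedonic scale.
HEDONIC_ATTRIBUTES = ("liking", "texture_liking")
#: Intensity attributes scored on the unipolar [0, +100] intensity scale.
INTENSITY_ATTRIBUTES = ("sweetness", "sourness", "flavor_intensity")
ALL_ATTRIBUTES = HEDONIC_ATTRIBUTES + INTENSITY_ATTRIBUTES

COMPOUND_CLASSES = (
    "sugar",
    "acid",
    "ester",
    "aldehyde",
    "ketone",
    "lactone",
    "alcohol",
    "terpene",
    "furan",
    "other",
)


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def attribute_bounds(attribute: str) -> tuple[float, float]:
    """Scale bounds for a sensory attribute (hedonic or intensity)."""
    if attribute in HEDONIC_ATTRIBUTES:
        return (-100.0, 100.0)
    if attribute in INTENSITY_ATTRIBUTES:
        return (0.0, 100.0)
    raise KeyError(f"unknown attribute {attribute!r}")


@dataclass
class PanelRatings:
    """Long-format consumer panel ratings.

    ``records`` has columns ``panelist_id, session_id, sample_id, attribute,
    score``.  Hedonic scores live in [-100, 100], intensity scores in
    [0, 100]; a (panelist, sample, attribute) triple is unique within a
    session.
    """

    records: pd.DataFrame

    REQUIRED = ("panelist_id", "session_id", "sample_id", "attribute", "score")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        rec = self.records.reset_index(drop=True)
        bad_attr = set(rec["attribute"]) - set(ALL_ATTRIBUTES)
        if bad_attr:
            raise ValidationError(f"unknown attributes: {sorted(bad_attr)}")
        score = pd.to_numeric(rec["score"], errors="coerce")
        nonnum = rec.index[score.isna() & rec["score"].notna()]
        if len(nonnum):
            raise ValidationError(f"non-numeric score at row {nonnum[0]}")
        rec["score"] = score
        for attrs, (lo, hi) in (
            (HEDONIC_ATTRIBUTES, (-100.0, 100.0)),
            (INTENSITY_ATTRIBUTES, (0.0, 100.0)),
        ):
            sel = rec["attribute"].isin(attrs)
            bad = rec.index[sel & ((score < lo) | (score > hi))]
            if len(bad):
                raise ValidationError(
                    f"score out of [{lo}, {hi}] at row {bad[0]} "
                    f"(attribute {rec.loc[bad[0], 'attribute']!r}, "
                    f"score {rec.loc[bad[0], 'score']})"
                )
        dup = rec.duplicated(
            ["session_id", "panelist_id", "sample_id", "attribute"]
        )
        if dup.any():
            raise ValidationError(
                f"duplicate (panelist, sample, attribute) at row {rec.index[dup][0]}"
            )
        self.records = rec

    @property
    def samples(self) -> list:
        return sorted(self.records["sample_id"].unique())

    @property
    def attributes(self) -> list:
        return sorted(self.records["attribute"].unique())

    def raw_sample_means(self) -> pd.DataFrame:
        """Unadjusted per-sample mean score, sample x attribute."""
        return self.records.pivot_table(
            index="sample_id", columns="attribute", values="score", aggfunc="mean"
        )


@dataclass
class ChemicalMatrix:
    """Sample x compound abundance matrix with period and class annotations.

    ``abundance`` holds non-negative values where detected and NaN where the
    compound was not detected for that sample; ``period`` maps each sample to
    exactly one technical period; ``compound_class`` maps each compound to a
    chemical class.  Volatile abundances are emission rates
    (ng 100 gFW^-1 h^-1); sugars and acids are concentrations
    (mg 100 gFW^-1).  Units are never mixed downstream because all analyses
    run on autoscaled values.
    """

    abundance: pd.DataFrame
    period: pd.Series
    compound_class: pd.Series
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.abundance.columns.duplicated().any():
            raise ValidationError("duplicate compound ids")
        if self.abundance.index.duplicated().any():
            raise ValidationError("duplicate sample ids")
        self.period = self.period.reindex(self.abundance.index)
        if self.period.isna().any():
            missing = self.period.index[self.period.isna()][0]
            raise ValidationError(f"sample {missing!r} has no period label")
        self.compound_class = self.compound_class.reindex(self.abundance.columns)
        if self.compound_class.isna().any():
            missing = self.compound_class.index[self.compound_class.isna()][0]
            raise ValidationError(f"compound {missing!r} has no class")
        bad_class = set(self.compound_class) - set(COMPOUND_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown compound classes: {sorted(bad_class)}")
        vals = self.abundance.to_numpy(dtype=float)
        if (vals[np.isfinite(vals)] < 0).any():
            raise ValidationError("negative abundance where detected")

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean detection mask, same shape as ``abundance``."""
        return self.abundance.notna()

    @property
    def periods(self) -> list:
        return sorted(self.period.unique())

    @property
    def compounds(self) -> list:
        return list(self.abundance.columns)

    def compounds_of_class(self, *classes: str) -> list:
        return [c for c in self.compounds if self.compound_class[c] in classes]

    def period_detection(self) -> pd.DataFrame:
        """period x compound mask: compound detected in >= 1 sample of period."""
        return self.detected.groupby(self.period).any()

    def fold_ranges(self) -> pd.Series:
        """(max detected) / (min detected) per compound; NaN if < 2 detections."""
        mx = self.abundance.max()
        mn = self.abundance.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            out = mx / mn
        out[self.detected.sum() < 2] = np.nan
        return out


@dataclass
class ScaledMatrix:
    """Per-period autoscaled chemical matrix (dimensionless z-scores).

    ``provenance`` records the period means and SDs used, so scaling is
    invertible and idempotence can be checked.  Within each period every
    retained compound has mean 0 and sample SD 1 over the samples where it is
    defined.
    """

    values: pd.DataFrame
    period: pd.Series
    compound_class: pd.Series
    period_means: pd.DataFrame = field(default=None)  # period x compound
    period_sds: pd.DataFrame = field(default=None)
    dropped: list = field(default_factory=list)  # (compound, period) pairs
    sample_meta: pd.DataFrame | None = None

    @property
    def detected(self) -> pd.DataFrame:
        return self.values.notna()

    @property
    def periods(self) -> list:
        return sorted(self.period.unique())

    @property
    def compounds(self) -> list:
        return list(self.values.columns)

    def compounds_of_class(self, *classes: str) -> list:
        return [c for c in self.compounds if self.compound_class[c] in classes]

    def period_detection(self) -> pd.DataFrame:
        return self.detected.groupby(self.period).any()


@dataclass
class GenotypeMatrix:
    """Sample x marker dosage matrix (0/1/2, NaN for missing) with a map."""

    dosage: pd.DataFrame
    marker_map: pd.DataFrame  # index marker_id, columns linkage_group, position

    def __post_init__(self) -> None:
        vals = self.dosage.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ValidationError("dosages must be 0/1/2 or missing")
        self.marker_map = self.marker_map.reindex(self.dosage.columns)
        if "position" in self.marker_map and (self.marker_map["position"] < 0).any():
            raise ValidationError("negative marker position")

    @property
    def markers(self) -> list:
        return list(self.dosage.columns)
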