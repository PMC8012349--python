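"""Reading/writing study tables, per-period autoscaling and period merging.

Chemical tables travel as two CSV/TSV files: a wide abundance table
(``sample_id, period, <compound columns>``, empty cells = not detected) and a
compound metadata table (``compound_id, class``).  Sensory ratings travel as
one long table.  Autoscaling (per-compound z-scoring within each technical
period) is the normalization applied before any correlation, clustering or
regression; period merging computes the compound set shared by all periods.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from flavoromics.containers import (
    ChemicalMatrix,
    GenotypeMatrix,
    PanelRatings,
    ScaledMatrix,
    ValidationError,
    attribute_bounds,
)

log = logging.getLogger(__name__)

_DIALECTS = {"csv": ",", "tsv": "\t"}


class ParseError(ValueError):
    """Raised for malformed input files, citing the offending row."""


class EmptyIntersectionError(ValueError):
    """Raised when period merging in common mode retains no compound."""


def _sep(dialect: str) -> str:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")


def read_sensory(path, dialect: str = "csv") -> PanelRatings:
    """Read long-format panel ratings, validating scales row by row."""
    df = pd.read_csv(path, sep=_sep(dialect))
    missing = [c for c in PanelRatings.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    score = pd.to_numeric(df["score"], errors="coerce")
    bad = df.index[score.isna()]
    if len(bad):
        raise ParseError(f"{path}: non-numeric score at row {bad[0] + 2}")
    df["score"] = score
    from flavoromics.containers import ALL_ATTRIBUTES

    unknown = ~df["attribute"].isin(ALL_ATTRIBUTES)
    if unknown.any():
        i = df.index[unknown][0]
        raise ParseError(
            f"{path}: unknown attribute {df.loc[i, 'attribute']!r} at row {i + 2}"
        )
    bad = pd.Series(False, index=df.index)
    for attr in df["attribute"].unique():
        lo, hi = attribute_bounds(attr)
        sel = df["attribute"] == attr
        bad |= sel & ~df["score"].between(lo, hi)
    if bad.any():
        i = df.index[bad][0]
        lo, hi = attribute_bounds(df.loc[i, "attribute"])
        raise ParseError(
            f"{path}: score {df.loc[i, 'score']} outside [{lo}, {hi}] "
            f"at row {i + 2}"
        )
    try:
        return PanelRatings(df)
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_sensory(ratings: PanelRatings, path, dialect: str = "csv") -> None:
    ratings.records.to_csv(path, sep=_sep(dialect), index=False)


def read_chemicals(path, meta_path, dialect: str = "csv") -> ChemicalMatrix:
    """Read a wide abundance table plus a compound metadata table."""
    df = pd.read_csv(path, sep=_sep(dialect))
    for col in ("sample_id", "period"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    meta = pd.read_csv(meta_path, sep=_sep(dialect))
    for col in ("compound_id", "class"):
        if col not in meta.columns:
            raise ParseError(f"{meta_path}: missing column {col!r}")
    df = df.set_index("sample_id")
    period = df.pop("period")
    extra = [c for c in df.columns if c in ("session", "genotype", "temperature")]
    sample_meta = df[extra] if extra else None
    ab = df.drop(columns=extra).apply(pd.to_numeric, errors="coerce")
    neg = ab.lt(0)
    if neg.any().any():
        col = neg.any()[neg.any()].index[0]
        row = neg.index[neg[col]][0]
        raise ParseError(f"{path}: negative abundance for {col!r} in sample {row!r}")
    classes = meta.set_index("compound_id")["class"]
    unknown = [c for c in ab.columns if c not in classes.index]
    if unknown:
        raise ParseError(f"{meta_path}: no class for compounds {unknown[:5]}")
    try:
        return ChemicalMatrix(
            abundance=ab,
            period=period,
            compound_class=classes.reindex(ab.columns),
            sample_meta=sample_meta,
        )
    except ValidationError as e:
        raise ParseError(f"{path}: {e}") from e


def write_chemicals(chem: ChemicalMatrix, path, meta_path, dialect: str = "csv") -> None:
    sep = _sep(dialect)
    out = chem.abundance.copy()
    out.insert(0, "period", chem.period)
    if chem.sample_meta is not None:
        for i, c in enumerate(chem.sample_meta.columns):
            out.insert(1 + i, c, chem.sample_meta[c])
    out.to_csv(path, sep=sep, index_label="sample_id")
    pd.DataFrame(
        {"compound_id": chem.compounds,
         "class": chem.compound_class.reindex(chem.compounds)}
    ).to_csv(meta_path, sep=sep, index=False)


def read_genotypes(path, map_path=None, dialect: str = "csv") -> GenotypeMatrix:
    """Read a samples x markers dosage CSV and an optional marker map."""
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    if map_path is not None:
        mmap = pd.read_csv(map_path, sep=_sep(dialect), index_col=0)
    else:
        mmap = pd.DataFrame(
            {"linkage_group": "NA", "position": np.arange(df.shape[1], dtype=float)},
            index=df.columns,
        )
    return GenotypeMatrix(dosage=df, marker_map=mmap)


def write_genotypes(g: GenotypeMatrix, path, map_path, dialect: str = "csv") -> None:
    sep = _sep(dialect)
    g.dosage.to_csv(path, sep=sep, index_label="sample_id")
    g.marker_map.to_csv(map_path, sep=sep, index_label="marker_id")


def autoscale_by_period(
    chem: ChemicalMatrix | ScaledMatrix,
    impute: str = "none",
    log_transform: bool = False,
) -> ScaledMatrix:
    """z-score each compound within each period (sample SD, n-1 denominator).

    Compounds constant (or detected < 2 times) within a period are dropped
    from that period with a warning; they stay available in other periods.
    ``impute='min_z'`` fills sample-level missing values with the compound's
    minimum z-score in that period (for correlation/PLS input);
    ``impute='none'`` leaves them missing.  ``log_transform`` applies log
    before scaling (only valid for raw abundances).
    """
    values = (
        chem.abundance.astype(float)
        if isinstance(chem, ChemicalMatrix)
        else chem.values.astype(float)
    )
    if log_transform:
        if isinstance(chem, ScaledMatrix):
            raise ValueError("log_transform applies to raw abundances only")
        values = np.log(values)
    if impute not in ("none", "min_z"):
        raise ValueError(f"unknown impute mode {impute!r}")

    periods = sorted(chem.period.unique())
    out = values.copy()
    means = pd.DataFrame(index=periods, columns=values.columns, dtype=float)
    sds = pd.DataFrame(index=periods, columns=values.columns, dtype=float)
    dropped: list[tuple] = []
    for p in periods:
        rows = chem.period == p
        block = values.loc[rows.values]
        m = block.mean()
        s = block.std(ddof=1)
        n_det = block.notna().sum()
        bad = (n_det >= 1) & ((n_det < 2) | (s < 1e-12) | s.isna())
        for c in values.columns[bad]:
            dropped.append((c, p))
            warnings.warn(
                f"compound {c!r} constant or under-detected in period {p!r}; "
                "dropped from that period",
                stacklevel=2,
            )
        z = (block - m) / s
        z.loc[:, bad] = np.nan
        if impute == "min_z":
            z = z.fillna(z.min())
        out.loc[rows.values] = z
        means.loc[p] = m
        sds.loc[p] = s
    all_missing = out.notna().sum() == 0
    if all_missing.any():
        log.warning(
            "compounds with no usable period: %s", list(values.columns[all_missing])
        )
    return ScaledMatrix(
        values=out,
        period=chem.period.copy(),
        compound_class=chem.compound_class.copy(),
        period_means=means,
        period_sds=sds,
        dropped=dropped,
        sample_meta=getattr(chem, "sample_meta", None),
    )


def merge_periods(scaled: ScaledMatrix, mode: str = "common") -> tuple[ScaledMatrix, pd.DataFrame]:
    """Merge the per-period blocks; in ``common`` mode keep compounds present
    in every period.

    Presence means detected in at least one sample of the period (after any
    per-period drops).  Returns the merged matrix and an intersection report
    counting retained compounds by chemical class.
    """
    periods = scaled.periods
    if len(periods) < 2:
        raise ValueError("merge_periods requires >= 2 periods")
    if mode not in ("common", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    pres = scaled.period_detection()
    if mode == "common":
        keep = pres.all(axis=0)
    else:
        keep = pres.any(axis=0)
    kept = list(scaled.values.columns[keep])
    if not kept:
        raise EmptyIntersectionError(
            "no compound is detected in every period; per-period compound "
            f"counts: {pres.sum(axis=1).to_dict()}"
        )
    merged = ScaledMatrix(
        values=scaled.values[kept],
        period=scaled.period.copy(),
        compound_class=scaled.compound_class.reindex(kept),
        period_means=(
            scaled.period_means[kept] if scaled.period_means is not None else None
        ),
        period_sds=(
            scaled.period_sds[kept] if scaled.period_sds is not None else None
        ),
        dropped=list(scaled.dropped),
        sample_meta=scaled.sample_meta,
    )
    report = (
        merged.compound_class.value_counts()
        .rename_axis("class")
        .to_frame("n_compounds")
        .reset_index()
    )
    return merged, report
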