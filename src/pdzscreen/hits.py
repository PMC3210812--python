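"""Duplicate-spot protein-array hit calling.

The processing chain mirrors single-channel functional protein-array
practice: local-background correction, LOWESS de-trending of the log2
signal against print order, locally weighted adjustment for the printed
protein concentration, slide-relative Z-scores, and the duplicate-spot
decision rule -- a protein is a hit on a slide when the average Z of its
two spots exceeds 3 and the coefficient of variation of the two replicate
signals is below 0.5.  Hits reproducible across slides are the
intersection of the per-slide hit sets.

Spot tables are held as pandas DataFrames with canonical columns
``slide_id, block, row, col, protein_id, replicate_index, fg, bg, conc``;
processing appends ``net, norm, adj, z``.  Blank spots (``conc == 0``)
are excluded from every fit and are never callable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import FormatError, IntegrityError, ProcessingError, UsageError

logger = logging.getLogger(__name__)

#: GenePix-Results-style header -> canonical column names.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "Block": "block",
    "Row": "row",
    "Column": "col",
    "ID": "protein_id",
    "F635 Median": "fg",
    "B635 Median": "bg",
    "Concentration": "conc",
}

CANONICAL_COLUMNS = ["slide_id", "block", "row", "col", "protein_id",
                     "replicate_index", "fg", "bg", "conc"]

Z_THRESHOLD = 3.0
CV_THRESHOLD = 0.5


def read_spot_table(path: str | Path, column_map: Mapping[str, str] | None = None,
                    slide_id: str | None = None) -> pd.DataFrame:
    """Read a GenePix-Results-style TSV into the canonical spot frame.

    ``column_map`` maps file headers to canonical names (defaults to the
    GenePix names).  ``replicate_index`` is assigned 1, 2, ... in order of
    appearance within each protein.
    """
    path = Path(path)
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df.rename(columns=column_map)[list(column_map.values())]
    df.insert(0, "slide_id", slide_id if slide_id is not None else path.stem)
    if df.empty:
        logger.warning("%s: empty data section", path)
        df["replicate_index"] = pd.Series(dtype=int)
        return df[CANONICAL_COLUMNS]
    dup = df.duplicated(subset=["block", "row", "col"])
    if dup.any():
        where = df.loc[dup, ["block", "row", "col"]].iloc[0].tolist()
        raise IntegrityError(f"{path}: duplicate spot coordinate {where}")
    df["replicate_index"] = df.groupby("protein_id").cumcount() + 1
    return df[CANONICAL_COLUMNS]


def from_genepix_frame(table: pd.DataFrame, slide_id: str) -> pd.DataFrame:
    """Convert an in-memory GenePix-style table (e.g. simulator output)."""
    df = table.rename(columns=dict(DEFAULT_COLUMN_MAP))
    df = df[[c for c in df.columns if c in set(DEFAULT_COLUMN_MAP.values())]].copy()
    df.insert(0, "slide_id", slide_id)
    df["replicate_index"] = df.groupby("protein_id").cumcount() + 1
    return df[CANONICAL_COLUMNS]


def background_correct(spots: pd.DataFrame) -> pd.DataFrame:
    """Subtract local background; net signal is floored at zero."""
    out = spots.copy()
    out["net"] = np.clip(out["fg"].to_numpy(float) - out["bg"].to_numpy(float),
                         0.0, None)
    return out


def _per_slide(spots: pd.DataFrame):
    for slide, sub in spots.groupby("slide_id", sort=False):
        yield slide, sub


def lowess_detrend(spots: pd.DataFrame, frac: float = 0.3,
                   iters: int = 3) -> pd.DataFrame:
    """De-trend log2 net signal against row-major print order, per slide.

    ``norm = log2(net + 1) - fit + median(fit)`` where the fit is a locally
    weighted regression over spots ordered by (block, row, col).  Blank
    spots get ``norm = NaN``.
    """
    out = spots.copy()
    out["norm"] = np.nan
    for slide, sub in _per_slide(out):
        mask = sub["conc"] > 0
        if mask.sum() < 10:
            raise ProcessingError(
                f"slide {slide}: need >= 10 non-blank spots, got {int(mask.sum())}"
            )
        sub = sub.loc[mask]
        order = sub.sort_values(["block", "row", "col"]).index
        y = np.log2(sub.loc[order, "net"].to_numpy(float) + 1.0)
        x = np.arange(len(order), dtype=float)
        fit = lowess(y, x, frac=frac, it=iters, return_sorted=False)
        norm = y - fit + np.median(fit)
        out.loc[order, "norm"] = norm
    return out


def concentration_adjust(spots: pd.DataFrame, frac: float = 0.5) -> pd.DataFrame:
    """Remove the dependence of ``norm`` on printed concentration, per slide.

    ``adj = norm - g(log10 conc)`` with g a locally weighted regression
    fitted over all non-blank spots of the slide.  When every printed
    concentration is identical the adjustment degenerates to centering.
    """
    out = spots.copy()
    out["adj"] = np.nan
    for slide, sub in _per_slide(out):
        sub = sub.loc[sub["conc"] > 0]
        norm = sub["norm"].to_numpy(float)
        conc = sub["conc"].to_numpy(float)
        if np.unique(conc).size == 1:
            logger.info("slide %s: constant concentration; centering only", slide)
            out.loc[sub.index, "adj"] = norm - norm.mean()
            continue
        g = lowess(norm, np.log10(conc), frac=frac, it=3, return_sorted=False)
        out.loc[sub.index, "adj"] = norm - g
    return out


def slide_zscores(spots: pd.DataFrame, robust: bool = False) -> pd.DataFrame:
    """Z-score the adjusted values against the slide's spot population.

    Classical z uses the sample mean and n-1 standard deviation; the
    robust variant uses the median and 1.4826 x MAD.
    """
    out = spots.copy()
    out["z"] = np.nan
    for slide, sub in _per_slide(out):
        sub = sub.loc[sub["conc"] > 0]
        if len(sub) < 3:
            raise ProcessingError(f"slide {slide}: need >= 3 non-blank spots")
        adj = sub["adj"].to_numpy(float)
        if robust:
            center = np.median(adj)
            scale = 1.4826 * np.median(np.abs(adj - center))
        else:
            center = adj.mean()
            scale = adj.std(ddof=1)
        if scale == 0:
            raise ProcessingError(f"slide {slide}: zero variance in adjusted signal")
        out.loc[sub.index, "z"] = (adj - center) / scale
    return out


def call_hits(spots: pd.DataFrame, z_thresh: float = Z_THRESHOLD,
              cv_thresh: float = CV_THRESHOLD,
              cv_basis: str = "adjusted") -> pd.DataFrame:
    """Apply the duplicate-spot rule to one slide's processed spots.

    ``mean_z`` averages the duplicate pair's Z-scores; ``cv`` is the
    sample standard deviation over the two replicate signals divided by
    their mean (i.e. |s1 - s2| / sqrt(2) / mean).  The replicate signal is
    the concentration-adjusted value back-transformed to linear scale
    (``2**adj``) by default; ``cv_basis`` may instead be ``net`` or
    ``raw``.  A protein is a hit iff ``mean_z > z_thresh`` and
    ``cv < cv_thresh`` (both strict); zero-mean pairs get ``cv = inf``.
    """
    if cv_basis not in ("adjusted", "net", "raw"):
        raise UsageError(f"cv_basis must be adjusted|net|raw, got {cv_basis!r}")
    slides = spots["slide_id"].unique()
    if len(slides) != 1:
        raise UsageError("call_hits operates on a single slide")
    sub = spots.loc[spots["conc"] > 0]
    sizes = sub.groupby("protein_id").size()
    bad = sizes[sizes != 2]
    if len(bad):
        raise IntegrityError(
            f"proteins without exactly two replicate spots: {sorted(bad.index)}"
        )
    rows = []
    for pid, pair in sub.groupby("protein_id", sort=True):
        if cv_basis == "adjusted":
            s = np.power(2.0, pair["adj"].to_numpy(float))
        elif cv_basis == "net":
            s = pair["net"].to_numpy(float)
        else:
            s = pair["fg"].to_numpy(float)
        mean_s = s.mean()
        cv = float(s.std(ddof=1) / mean_s) if mean_s > 0 else np.inf
        mean_z = float(pair["z"].mean())
        rows.append((pid, slides[0], mean_z, cv,
                     bool(mean_z > z_thresh and cv < cv_thresh)))
    return pd.DataFrame(rows, columns=["protein_id", "slide_id", "mean_z",
                                       "cv", "is_hit"])


def reproducible_hits(hit_tables: Sequence[pd.DataFrame | Iterable[str]]) -> set[str]:
    """Intersect per-slide hit sets; requires at least two slides."""
    if len(hit_tables) < 2:
        raise UsageError("reproducible_hits needs hit lists from >= 2 slides")
    sets = []
    for t in hit_tables:
        if isinstance(t, pd.DataFrame):
            sets.append(set(t.loc[t["is_hit"], "protein_id"]))
        else:
            sets.append(set(t))
    return set.intersection(*sets)


def process_slide(spots: pd.DataFrame, lowess_frac: float = 0.3,
                  conc_frac: float = 0.5, robust: bool = False) -> pd.DataFrame:
    """Run background correction, de-trending, concentration adjustment
    and Z-scoring on one slide's spot frame."""
    return slide_zscores(
        concentration_adjust(
            lowess_detrend(background_correct(spots), frac=lowess_frac),
            frac=conc_frac,
        ),
        robust=robust,
    )


def run_hit_calling(slides: Sequence[pd.DataFrame], z_thresh: float = Z_THRESHOLD,
                    cv_thresh: float = CV_THRESHOLD, cv_basis: str = "adjusted",
                    robust: bool = False) -> tuple[list[pd.DataFrame], set[str]]:
    """Full pipeline over several slides; returns per-slide hit tables and
    the reproducible (dual-slide intersection) hit set."""
    tables = [call_hits(process_slide(s, robust=robust), z_thresh=z_thresh,
                        cv_thresh=cv_thresh, cv_basis=cv_basis) for s in slides]
    return tables, reproducible_hits(tables)
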