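"""Interactor-list assembly, filtering and category enrichment.

Operations on candidate-interactor rosters: removing hits whose cDNA does
not correspond to an annotated protein (3' UTR constructs, withdrawn or
suppressed GenBank records, nonsense-mediated-decay candidates), merging
interactor lists from multiple screens with provenance tracking,
pairwise-overlap accounting between screens, and the kinase-style
category-proportion comparison with a hypergeometric enrichment p-value.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .errors import UsageError, ValidationError

logger = logging.getLogger(__name__)

RECORD_STATUSES = frozenset(
    {"annotated", "utr3", "withdrawn", "suppressed_noncoding", "nmd_candidate"}
)
REMOVAL_STATUSES = tuple(sorted(RECORD_STATUSES - {"annotated"}))

SOURCE_TAGS = frozenset(
    {"protoarray", "y2h_this_study", "literature", "ht_y2h",
     "peptide_profile", "pdz_peptide_screen"}
)


@dataclass
class InteractorRecord:
    """One candidate interactor with provenance."""

    gene_id: str
    symbol: str = ""
    species: str = ""
    sources: set[str] = field(default_factory=set)
    record_status: str = "annotated"
    cterm: str | None = None
    categories: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class EnrichmentResult:
    """Category proportions among hits versus the screening background."""

    hits_in_category: int
    hits_total: int
    bg_in_category: int
    bg_total: int
    hit_pct: float
    bg_pct: float
    fold: float
    p_value: float


def _round_pct(numerator: int, denominator: int) -> float:
    # one decimal, round-half-even, as percentages are conventionally printed
    return float(round(100.0 * numerator / denominator, 1))


def filter_annotated(
    records: Sequence[InteractorRecord | Mapping],
) -> tuple[list, Counter]:
    """Keep records whose status is ``annotated``; tally the removals.

    Accepts :class:`InteractorRecord` objects or mappings with a
    ``record_status`` key.  The partition is exact:
    ``len(records) == len(kept) + sum(tally.values())``.
    """
    kept = []
    tally: Counter = Counter()
    for rec in records:
        status = rec.record_status if isinstance(rec, InteractorRecord) \
            else rec["record_status"]
        if status not in RECORD_STATUSES:
            raise ValidationError(f"unknown record_status {status!r}")
        if status == "annotated":
            kept.append(rec)
        else:
            tally[status] += 1
    return kept, tally


def merge_sources(
    *lists: Iterable[InteractorRecord],
) -> list[InteractorRecord]:
    """Unify interactor lists on gene_id; provenance sources are unioned.

    Symbol conflicts resolve to the first-seen symbol and are logged.
    The merge key is the gene identifier, never the symbol, and no
    cross-species mapping is attempted.
    """
    merged: dict[str, InteractorRecord] = {}
    for lst in lists:
        for rec in lst:
            if not rec.gene_id:
                raise ValidationError("record without gene_id cannot be merged")
            if rec.gene_id not in merged:
                merged[rec.gene_id] = InteractorRecord(
                    gene_id=rec.gene_id, symbol=rec.symbol, species=rec.species,
                    sources=set(rec.sources), record_status=rec.record_status,
                    cterm=rec.cterm, categories=set(rec.categories),
                )
                continue
            cur = merged[rec.gene_id]
            cur.sources |= set(rec.sources)
            cur.categories |= set(rec.categories)
            if rec.symbol and cur.symbol and rec.symbol != cur.symbol:
                logger.warning("gene %s: symbol conflict %r vs %r (keeping first)",
                               rec.gene_id, cur.symbol, rec.symbol)
            elif rec.symbol and not cur.symbol:
                cur.symbol = rec.symbol
            if cur.cterm is None and rec.cterm is not None:
                cur.cterm = rec.cterm
    return list(merged.values())


def overlap_counts(
    named_sets: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise overlap matrix and per-set shared fractions.

    Returns a symmetric |A n B| count matrix (diagonal = set sizes) and,
    for each set, the fraction of its members found in at least one other
    set.
    """
    if len(named_sets) < 2:
        raise UsageError("overlap_counts needs at least 2 sets")
    sets = {name: set(ids) for name, ids in named_sets.items()}
    names = list(sets)
    mat = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in names] for a in names],
        index=names, columns=names, dtype=int,
    )
    fractions = {}
    for name in names:
        others = set().union(*(sets[o] for o in names if o != name))
        fractions[name] = (len(sets[name] & others) / len(sets[name])
                           if sets[name] else 0.0)
    return mat, fractions


def domain_enrichment(
    hit_ids: Iterable[str],
    category_ids: Iterable[str],
    background_ids: Iterable[str],
) -> EnrichmentResult:
    """Compare a category's proportion among hits to the background.

    ``p_value`` is the upper-tail hypergeometric probability
    P(X >= hits_in_category) when drawing ``len(hits)`` proteins from the
    background.  The study itself reports the proportions only; the test
    is an added convenience for judging them.
    """
    hits = set(hit_ids)
    bg = set(background_ids)
    cat = set(category_ids)
    stray = hits - bg
    if stray:
        raise ValidationError(f"hits not in background: {sorted(stray)[:10]}")
    k = len(hits & cat)
    n = len(hits)
    big_k = len(bg & cat)
    big_n = len(bg)
    return enrichment_from_counts(k, n, big_k, big_n)


def enrichment_from_counts(hits_in_category: int, hits_total: int,
                           bg_in_category: int, bg_total: int) -> EnrichmentResult:
    """Build an :class:`EnrichmentResult` from the four counts directly."""
    if not (0 <= hits_in_category <= hits_total <= bg_total):
        raise ValidationError("inconsistent enrichment counts")
    if not (hits_in_category <= bg_in_category <= bg_total):
        raise ValidationError("inconsistent category counts")
    hit_pct = _round_pct(hits_in_category, hits_total)
    bg_pct = _round_pct(bg_in_category, bg_total)
    fold = hit_pct / bg_pct if bg_pct > 0 else float("inf")
    p = float(hypergeom.sf(hits_in_category - 1, bg_total, bg_in_category,
                           hits_total))
    return EnrichmentResult(hits_in_category, hits_total, bg_in_category,
                            bg_total, hit_pct, bg_pct, fold, p)


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["gene_id", "symbol", "species", "source", "record_status", "cterm"]


def read_interactor_tsv(path: str | Path) -> list[InteractorRecord]:
    """Read an interactor list (gene_id, symbol, species, source,
    record_status, cterm); ``source`` may hold several ;-separated tags."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("gene_id", "source") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(InteractorRecord(
            gene_id=row["gene_id"],
            symbol=row.get("symbol", ""),
            species=row.get("species", ""),
            sources={s for s in row["source"].split(";") if s},
            record_status=row.get("record_status", "annotated") or "annotated",
            cterm=row.get("cterm") or None,
        ))
    return records


def write_interactor_tsv(records: Sequence[InteractorRecord],
                         path: str | Path) -> None:
    rows = [{
        "gene_id": r.gene_id, "symbol": r.symbol, "species": r.species,
        "source": ";".join(sorted(r.sources)), "record_status": r.record_status,
        "cterm": r.cterm or "",
    } for r in records]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
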