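"""C-terminal PDZ-binding motif analysis.

PDZ domains read the extreme carboxy terminus of their ligands.  Positions
are numbered by the standard PDZ ligand convention: the C-terminal residue
is position 0 and positions -1, -2, ... count leftward.  The classes
implemented here are the ones relevant to LNX1 screening data:

* ``cys_terminal`` -- a cysteine at position 0 (the non-canonical ligand
  class selected by LNX1 PDZ2, e.g. S-X-C peptides);
* ``class1`` -- the canonical Class I motif S/T-X-Phi (Ser or Thr at -2
  and a hydrophobic residue at 0);
* ``hydrophobic_0`` -- a hydrophobic residue at 0 without the -2 Ser/Thr;
* ``other`` -- anything else.

Classes are mutually exclusive with precedence
``cys_terminal > class1 > hydrophobic_0 > other``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues counted as hydrophobic at position 0.  Glycine is included:
#: small aliphatic termini (e.g. ...VFG) behave as hydrophobic-0 ligands.
HYDROPHOBIC_0 = frozenset("AFGILMVWY")

#: Conservative substitution groups (standard physicochemical classes).
DEFAULT_SUBSTITUTION_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("ST"),
    frozenset("AVLIM"),
    frozenset("FYW"),
    frozenset("KRH"),
    frozenset("DE"),
    frozenset("NQ"),
    frozenset("C"),
    frozenset("G"),
    frozenset("P"),
)

#: Token used in wild-type columns for constructs whose cDNA is not
#: translated into an annotated protein.
NOT_TRANSLATED_TOKEN = "Not translated to protein"
WILD_TYPE_TOKEN = "WT"


@dataclass(frozen=True)
class CTerminus:
    """A C-terminal peptide; ``sequence[-1]`` is position 0."""

    protein_id: str
    sequence: str
    source: str = "array_construct"

    def residue(self, position: int) -> str:
        """Residue at a non-positive PDZ position (0 = C-terminus)."""
        if position > 0:
            raise ValidationError(f"PDZ positions are <= 0, got {position}")
        idx = len(self.sequence) - 1 + position
        if idx < 0:
            raise ValidationError(
                f"{self.protein_id}: sequence too short for position {position}"
            )
        return self.sequence[idx]


@dataclass(frozen=True)
class MotifCall:
    protein_id: str
    motif_class: str
    residue_0: str
    residue_minus2: str


@dataclass(frozen=True)
class BindingSite:
    """The 17 ligand-contacting residues of a PDZ domain, pre-extracted."""

    pdz_id: str
    site_sequence: str

    def __post_init__(self) -> None:
        if len(self.site_sequence) != 17:
            raise ValidationError(
                f"{self.pdz_id}: binding site must be 17 residues, "
                f"got {len(self.site_sequence)}"
            )


def _clean(sequence: str) -> str:
    return "".join(sequence.split()).replace("*", "").upper()


def _check_residues(sequence: str, protein_id: str) -> None:
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValidationError(
            f"{protein_id}: non-standard residue(s) {sorted(bad)} in {sequence!r}"
        )


def extract_cterm(sequence: str, n: int = 12, protein_id: str = "",
                  source: str = "array_construct") -> CTerminus:
    """Return the last ``min(n, len)`` residues as a :class:`CTerminus`.

    Whitespace and stop markers (``*``) are stripped and the sequence is
    upper-cased before the suffix is taken.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    cleaned = _clean(sequence)
    if not cleaned:
        raise ValidationError(f"{protein_id or '<sequence>'}: empty sequence")
    return CTerminus(protein_id=protein_id, sequence=cleaned[-n:], source=source)


def classify_cterm(cterm: CTerminus | str,
                   hydrophobic_set: frozenset[str] = HYDROPHOBIC_0) -> MotifCall:
    """Assign a C-terminus to a PDZ motif class.

    Precedence: terminal cysteine beats Class I beats plain hydrophobic-0.
    Requires at least three residues (positions -2..0).
    """
    if isinstance(cterm, str):
        cterm = CTerminus(protein_id="", sequence=_clean(cterm))
    _check_residues(cterm.sequence, cterm.protein_id or cterm.sequence)
    if len(cterm.sequence) < 3:
        raise ValidationError(
            f"{cterm.protein_id or cterm.sequence}: need >= 3 residues to classify"
        )
    r0 = cterm.residue(0)
    rm2 = cterm.residue(-2)
    if r0 == "C":
        cls = "cys_terminal"
    elif rm2 in "ST" and r0 in hydrophobic_set:
        cls = "class1"
    elif r0 in hydrophobic_set:
        cls = "hydrophobic_0"
    else:
        cls = "other"
    return MotifCall(protein_id=cterm.protein_id, motif_class=cls,
                     residue_0=r0, residue_minus2=rm2)


def compare_to_wildtype(array_cterm: CTerminus | str, wildtype_entry: str) -> str:
    """Compare an arrayed construct's C-terminus with the natural terminus.

    ``wildtype_entry`` is either the token ``WT`` (the construct ends where
    the natural protein ends), an explicit wild-type sequence, or the token
    ``Not translated to protein`` for cDNAs without an annotated product.

    Returns one of ``natural_terminus``, ``artificial_tail``,
    ``not_translated``.
    """
    if wildtype_entry is None or not str(wildtype_entry).strip():
        raise ValidationError("missing wild-type entry")
    entry = " ".join(str(wildtype_entry).split())
    if entry.lower() == NOT_TRANSLATED_TOKEN.lower():
        return "not_translated"
    if entry.upper() == WILD_TYPE_TOKEN:
        return "natural_terminus"
    array_seq = array_cterm.sequence if isinstance(array_cterm, CTerminus) \
        else _clean(array_cterm)
    return "natural_terminus" if _clean(entry) == array_seq else "artificial_tail"


def _group_index(groups: Sequence[frozenset[str]]) -> Mapping[str, int]:
    index: dict[str, int] = {}
    for i, g in enumerate(groups):
        for aa in g:
            index[aa] = i
    return index


def conservative_match(
    query_cterm: CTerminus | str,
    candidates: Iterable[CTerminus],
    substitution_groups: Sequence[frozenset[str]] = DEFAULT_SUBSTITUTION_GROUPS,
) -> list[str]:
    """Find candidates whose final three residues match the query's up to
    conservative substitution.

    A candidate matches iff at each of positions -2, -1 and 0 its residue
    lies in the same substitution group as the query's residue.  Exact
    suffix matches therefore always match.
    """
    if isinstance(query_cterm, str):
        query_cterm = CTerminus(protein_id="query", sequence=_clean(query_cterm))
    index = _group_index(substitution_groups)

    def groups_of(ct: CTerminus) -> tuple[int, int, int]:
        if len(ct.sequence) < 3:
            raise ValidationError(f"{ct.protein_id}: need >= 3 C-terminal residues")
        out = []
        for pos in (-2, -1, 0):
            aa = ct.residue(pos)
            if aa not in index:
                raise ValidationError(
                    f"{ct.protein_id}: residue {aa!r} not in any substitution group"
                )
            out.append(index[aa])
        return tuple(out)  # type: ignore[return-value]

    target = groups_of(query_cterm)
    return [c.protein_id for c in candidates if groups_of(c) == target]


def binding_site_identity(site_a: BindingSite, site_b: BindingSite,
                          transfer_threshold: float = 70.0) -> tuple[float, bool]:
    """Percent identity over the 17 binding-site residues and whether the
    specificity-transfer rule applies (identity strictly above 70%)."""
    matches = sum(a == b for a, b in zip(site_a.site_sequence, site_b.site_sequence))
    identity = 100.0 * matches / 17
    return identity, identity > transfer_threshold
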