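"""Bundled study datasets for the LNX1 PDZ interactome screen.

These are the small, printed data tables of the LNX1 screening study:
the C-termini of the 21 ProtoArray interactors that carry candidate PDZ
recognition motifs (array construct vs. predicted natural terminus), the
six interactors from the yeast two-hybrid screen, the fourteen candidates
selected for co-immunoprecipitation, the protein-kinase content counts of
the array, and the record-status tally of the 62 reproducible array hits.

No raw slide scans or accession lists were deposited for the study, so
these printed values are the only real-data inputs the pipeline can be run
against; everything else is exercised with the synthetic generators.
"""

from __future__ import annotations

import pandas as pd

from .motif import NOT_TRANSLATED_TOKEN, WILD_TYPE_TOKEN, CTerminus, extract_cterm

# (protein, arrayed-construct C-terminus, wild-type comparison field)
_PROTOARRAY_TERMINI: tuple[tuple[str, str, str], ...] = (
    ("AMMECR1L", "RSVRSRSPHESV", NOT_TRANSLATED_TOKEN),
    ("AURKB", "RVLPPSALQSVA", WILD_TYPE_TOKEN),
    ("AURKC", "GRADPAFLYKVV", "RRVLPPCAQMAS"),
    ("C1ORF183", "PSGFDINTAVWV", WILD_TYPE_TOKEN),
    ("CAMK2N2", "LKGMGEKPPSGV", WILD_TYPE_TOKEN),
    ("DAPK1", "GRADPAFLYKVV", "TSYNSISSVVSR"),
    ("DEPDC6", "TIVMEVMEELEC", WILD_TYPE_TOKEN),
    ("EBF4", "SPARGLQGLAYS", NOT_TRANSLATED_TOKEN),
    ("EPHB3", "GRADPAFLYKVV", "RLQMNQTLPVQV"),
    ("IMAGE:4829245", "DKAMLELGPHIC", WILD_TYPE_TOKEN),
    ("KIAA1598", "IENVRETDSSNC", "AVDELKGILASQ"),
    ("MGC18299", "NKQNYTKPTTSV", WILD_TYPE_TOKEN),
    ("MRPS24", "QTVPSKVVYKYL", WILD_TYPE_TOKEN),
    ("MUSTN1", "KPKAGPTKSVFG", WILD_TYPE_TOKEN),
    ("NKD2", "WPGPFPSGLVAV", WILD_TYPE_TOKEN),
    ("PLEKHG5", "LLLNSTLTASEV", WILD_TYPE_TOKEN),
    ("PPID", "DKEKAVYAKMFA", WILD_TYPE_TOKEN),
    ("RASL11B", "ALSAKVRTVTSV", WILD_TYPE_TOKEN),
    ("SCLT1", "GELNGQLKYYQA", WILD_TYPE_TOKEN),
    ("SNCB", "PQEEYQEYEPEA", WILD_TYPE_TOKEN),
    ("ZADH2", "VVELPHSVNSKL", WILD_TYPE_TOKEN),
)

# Yeast two-hybrid interactors: (protein, Entrez gene id, C-terminus)
_Y2H_INTERACTORS: tuple[tuple[str, int, str], ...] = (
    ("WWP1", 11059, "FAIEETEGFGQE"),
    ("NG23", 401251, "GCTKGPRGPTRV"),
    ("PRA1", 10567, "AVDGEELQMEPV"),
    ("TP14C", 51522, "AKVGVSMFNRPH"),
    ("WAC", 51322, "LEKLKNQNSFMV"),
    ("Syntaxin5", 6811, "IVFFIIFVVFLA"),
)

# Candidates tested by co-immunoprecipitation:
# (protein, Entrez gene id, C-terminus, source, MF cluster or None)
_COIP_CANDIDATES: tuple[tuple[str, int, str, str, int | None], ...] = (
    ("ARVCF", 421, "GDAKPQPVDSWV", "peptide_profile", 1),
    ("claudin-1", 9076, "PAPSSGKDYV", "peptide_profile", 1),
    ("Claudin-3", 1365, "GTGYDRKDYV", "peptide_profile", 1),
    ("AURKB", 9212, "RVLPPSALQSVA", "protoarray", 4),
    ("CDK2", 1017, "QDVTKPVPHLRL", "protoarray", 4),
    ("MAPKAPK3", 7867, "GSSSASQGCNNQ", "protoarray", 4),
    ("PAK6", 56924, "QLYRKQTSTC", "peptide_profile", 4),
    ("PBK", 55872, "HIVEALETDV", "peptide_profile", 4),
    ("TYK2", 7297, "GQAPSVFSVC", "peptide_profile", 4),
    ("PKC-alpha1", 5578, "PQFVHPILQSAV", "pdz_peptide_screen", 4),
    ("KCNA4", 3739, "NCSNAKAVETDV", "peptide_profile", 7),
    ("PLEKHG5", 57449, "LLLNSTLTASEV", "protoarray", 9),
    ("RASL11B", 65997, "ALSAKVRTVTSV", "protoarray", None),
    ("CAMK2N2", 94032, "LKGMGEKPPSGV", "protoarray", None),
)

#: Protein-kinase content of the array versus the reproducible hit list:
#: 11 of the 62 dual-slide hits carry kinase domains, against 448 kinases
#: among the 8000 arrayed proteins.
ARRAY_KINASE_COUNTS = {
    "hits_in_category": 11,
    "hits_total": 62,
    "bg_in_category": 448,
    "bg_total": 8000,
}

#: Record-status breakdown of the 62 reproducible array hits: 4 constructs
#: mapped to 3' UTRs, 3 to cDNAs withdrawn during genome re-annotation,
#: 1 to a suppressed non-coding record, 1 to a nonsense-mediated-decay
#: candidate; the remaining 53 correspond to annotated proteins.
HIT_STATUS_TALLY = {
    "annotated": 53,
    "utr3": 4,
    "withdrawn": 3,
    "suppressed_noncoding": 1,
    "nmd_candidate": 1,
}


def protoarray_termini() -> pd.DataFrame:
    """The 21 motif-bearing ProtoArray hit C-termini.

    Columns: ``protein_id``, ``array_cterm`` (the 12 C-terminal residues of
    the arrayed construct) and ``wildtype`` (``WT``, an explicit natural
    terminus that differs from the construct, or the not-translated token).
    """
    return pd.DataFrame(_PROTOARRAY_TERMINI,
                        columns=["protein_id", "array_cterm", "wildtype"])


def protoarray_termini_records(n: int = 12) -> list[CTerminus]:
    """The arrayed-construct termini as :class:`~pdzscreen.motif.CTerminus`."""
    return [extract_cterm(seq, n=n, protein_id=pid, source="array_construct")
            for pid, seq, _wt in _PROTOARRAY_TERMINI]


def y2h_interactors() -> pd.DataFrame:
    """The six LNX1 interactors from the yeast two-hybrid screen."""
    return pd.DataFrame(_Y2H_INTERACTORS,
                        columns=["protein_id", "gene_id", "cterm"])


def coip_candidates() -> pd.DataFrame:
    """The fourteen proteins selected for co-immunoprecipitation testing."""
    return pd.DataFrame(
        _COIP_CANDIDATES,
        columns=["protein_id", "gene_id", "cterm", "source", "mf_cluster"],
    )


def synthetic_hit_roster() -> pd.DataFrame:
    """A synthetic stand-in for the 62-protein reproducible hit roster.

    The study reports only the status tally of the 62 dual-slide hits, not
    which protein carried which status, so this roster assigns placeholder
    identifiers with exactly the reported status counts (53 annotated,
    4 utr3, 3 withdrawn, 1 suppressed_noncoding, 1 nmd_candidate).  It is
    synthetic data: suitable for exercising the annotation filter, not a
    reconstruction of the study's supplementary hit list.
    """
    rows = []
    i = 1
    for status, count in HIT_STATUS_TALLY.items():
        for _ in range(count):
            rows.append((f"HIT{i:03d}", status))
            i += 1
    return pd.DataFrame(rows, columns=["protein_id", "record_status"])
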