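"""Synthetic inputs for exercising the screening pipeline end to end.

Three generators mirror the three kinds of input the real study consumed
but did not deposit:

* :func:`simulate_array_experiment` -- duplicate-spot, single-channel
  protein-array slides with a log-normal background, a smooth spatial
  trend, concentration-dependent signal and a set of planted binders;
* :func:`simulate_go_corpus` -- a toy ontology DAG (OBO 1.2) with latent
  protein groups annotating inside their own subtrees (GAF 2.1);
* :func:`simulate_termini` -- C-terminal 12-mers with planted Class I and
  terminal-cysteine PDZ motifs.

Each generator is deterministic for a fixed seed and emits a
machine-readable truth table alongside the data so that parameter-recovery
tests can score the pipeline against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .motif import HYDROPHOBIC_0

GENEPIX_COLUMNS = ["Block", "Row", "Column", "ID", "Name",
                   "F635 Median", "B635 Median", "Concentration"]

AMINO_ACIDS_20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# protein array
# ---------------------------------------------------------------------------

@dataclass
class ArraySimConfig:
    """Conditions for a duplicate-spot array simulation.

    The defaults reproduce the planted-recovery study conditions used
    throughout the test suite: 200 proteins, 10 planted binders at an
    8-fold signal boost, two replicate slides.
    """

    n_proteins: int = 200
    n_slides: int = 2
    n_planted: int = 10
    effect_size: float = 8.0          # fold net-signal boost for planted binders
    bg_log_mean: float = math.log(500.0)   # log-normal background, natural log
    bg_log_sd: float = 0.3
    spatial_amp: float = 0.3          # smooth trend amplitude, fraction of background
    replicate_noise_cv: float = 0.1   # within-duplicate multiplicative noise
    bg_est_cv: float = 0.05           # error of the reported local-background estimate
    conc_range: tuple[float, float] = (5.0, 50.0)  # printed conc, ng/uL
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if self.n_slides < 1:
            raise ConfigurationError("n_slides must be >= 1")
        if not 0 <= self.n_planted <= self.n_proteins:
            raise ConfigurationError("n_planted must satisfy 0 <= n_planted <= n_proteins")
        if self.effect_size < 1:
            raise ConfigurationError("effect_size must be >= 1")
        for name in ("bg_log_sd", "spatial_amp", "replicate_noise_cv", "bg_est_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.spatial_amp >= 1:
            raise ConfigurationError("spatial_amp must be < 1 (background stays positive)")
        lo, hi = self.conc_range
        if not (0 < lo <= hi):
            raise ConfigurationError("conc_range must satisfy 0 < low <= high")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_array_experiment(
    cfg: ArraySimConfig,
) -> tuple[list[pd.DataFrame], list[str]]:
    """Simulate duplicate-spot slides; return (per-slide tables, planted IDs).

    Each slide table uses GenePix-Results-style columns
    (``Block, Row, Column, ID, Name, F635 Median, B635 Median,
    Concentration``) with every protein printed twice in adjacent columns.
    Planted binders receive a net signal whose expectation is
    ``effect_size`` times the mean background at their spot, modulated by
    a sqrt(concentration) dependence with unit mean across the slide.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins

    # row-major layout, duplicates side by side
    pair_cols = max(1, math.ceil(math.sqrt(n)))
    n_rows = math.ceil(n / pair_cols)
    n_cols = 2 * pair_cols

    protein_ids = np.array([f"P{i:04d}" for i in range(1, n + 1)])
    planted_idx = np.sort(rng.choice(n, size=cfg.n_planted, replace=False))
    planted = np.zeros(n, dtype=bool)
    planted[planted_idx] = True

    lo, hi = cfg.conc_range
    conc = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    conc_scale = np.sqrt(conc)
    conc_scale = conc_scale / conc_scale.mean()

    bg_mean = math.exp(cfg.bg_log_mean + 0.5 * cfg.bg_log_sd ** 2)
    boost = np.where(planted, cfg.effect_size, 1.0)

    slides: list[pd.DataFrame] = []
    for _slide in range(cfg.n_slides):
        prot = np.repeat(np.arange(n), 2)
        grid_row = prot // pair_cols + 1
        grid_col = 2 * (prot % pair_cols) + 1 + np.tile([0, 1], n)
        trend = 1.0 + cfg.spatial_amp * 0.5 * (
            np.sin(2 * np.pi * grid_row / n_rows) + np.cos(2 * np.pi * grid_col / n_cols)
        )
        bg_reported = trend * rng.lognormal(cfg.bg_log_mean, cfg.bg_log_sd, size=2 * n)
        bg_actual = bg_reported * _lognormal_unit_mean(rng, cfg.bg_est_cv, 2 * n)
        # binding signal sees the pair-mean trend so duplicates differ only
        # by replicate noise (CV of the duplicate signal is 0 when
        # replicate_noise_cv = 0)
        pair_trend = np.repeat(trend.reshape(n, 2).mean(axis=1), 2)
        signal = (
            boost[prot] * bg_mean * pair_trend * conc_scale[prot]
            * _lognormal_unit_mean(rng, cfg.replicate_noise_cv, 2 * n)
        )
        fg = bg_actual + signal
        rows_out = pd.DataFrame({
            "Block": 1,
            "Row": grid_row,
            "Column": grid_col,
            "ID": protein_ids[prot],
            "Name": protein_ids[prot],
            "F635 Median": np.rint(fg).astype(np.int64),
            "B635 Median": np.rint(bg_reported).astype(np.int64),
            "Concentration": np.round(conc[prot], 3),
        })
        slides.append(rows_out)
    return slides, [str(p) for p in protein_ids[planted]]


def write_array_experiment(slides: list[pd.DataFrame], truth: list[str],
                           outdir: str | Path) -> list[Path]:
    """Write per-slide spot tables and the planted-binder truth as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tab in enumerate(slides, start=1):
        p = outdir / f"slide{i}.tsv"
        tab.to_csv(p, sep="\t", index=False)
        paths.append(p)
    truth_path = outdir / "truth_planted.tsv"
    pd.DataFrame({"protein_id": truth}).to_csv(truth_path, sep="\t", index=False)
    paths.append(truth_path)
    return paths


# ---------------------------------------------------------------------------
# GO corpus
# ---------------------------------------------------------------------------

_NAMESPACE_ASPECT = {"biological_process": "P", "molecular_function": "F",
                     "cellular_component": "C"}


@dataclass
class GoSimConfig:
    """Conditions for a group-structured ontology/annotation corpus."""

    n_groups: int = 3
    proteins_per_group: int = 8
    subtree_depth: int = 3        # levels below each group's root term
    branching: int = 3
    noise_p: float = 0.05         # chance a direct annotation leaves the group subtree
    terms_per_protein: int = 6
    namespace: str = "biological_process"
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if self.proteins_per_group < 1:
            raise ConfigurationError("proteins_per_group must be >= 1")
        if self.subtree_depth < 1 or self.branching < 1:
            raise ConfigurationError("subtree_depth and branching must be >= 1")
        if not 0.0 <= self.noise_p <= 1.0:
            raise ConfigurationError("noise_p must lie in [0, 1]")
        if self.terms_per_protein < 1:
            raise ConfigurationError("terms_per_protein must be >= 1")
        if self.namespace not in _NAMESPACE_ASPECT:
            raise ConfigurationError(f"unknown namespace {self.namespace!r}")
        subtree_size = sum(self.branching ** d for d in range(self.subtree_depth + 1))
        if self.terms_per_protein > subtree_size:
            raise ConfigurationError(
                f"terms_per_protein={self.terms_per_protein} exceeds the "
                f"{subtree_size}-term group subtree; deepen or widen the subtree"
            )


@dataclass
class GoCorpus:
    """A simulated ontology + annotation corpus with group truth."""

    obo_text: str
    gaf_text: str
    truth: pd.DataFrame                      # protein_id, group
    group_terms: dict[int, list[str]] = field(repr=False, default_factory=dict)
    annotations: dict[str, set[str]] = field(repr=False, default_factory=dict)

    def write(self, outdir: str | Path) -> tuple[Path, Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        obo = outdir / "ontology.obo"
        gaf = outdir / "annotations.gaf"
        truth = outdir / "truth_groups.tsv"
        obo.write_text(self.obo_text)
        gaf.write_text(self.gaf_text)
        self.truth.to_csv(truth, sep="\t", index=False)
        return obo, gaf, truth


def simulate_go_corpus(cfg: GoSimConfig) -> GoCorpus:
    """Simulate an ontology with latent protein groups.

    The DAG has one namespace root; each latent group owns a subtree of
    depth ``subtree_depth`` and branching factor ``branching`` hanging off
    the root.  Occasional extra is_a edges to shallower terms of the same
    subtree make the graph a genuine DAG rather than a tree.  Each protein
    draws ``terms_per_protein`` distinct direct annotations, each from its
    own group's subtree with probability ``1 - noise_p`` and from another
    group's subtree otherwise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ns = cfg.namespace
    aspect = _NAMESPACE_ASPECT[ns]

    counter = 1

    def new_term() -> str:
        nonlocal counter
        term = f"GO:{counter:07d}"
        counter += 1
        return term

    root = new_term()
    terms: dict[str, dict] = {root: {"name": f"{ns} root", "parents": []}}
    group_terms: dict[int, list[str]] = {}
    for g in range(cfg.n_groups):
        g_root = new_term()
        terms[g_root] = {"name": f"group{g} process", "parents": [root]}
        members = [g_root]
        level = [g_root]
        for depth in range(cfg.subtree_depth):
            nxt = []
            for parent in level:
                for b in range(cfg.branching):
                    t = new_term()
                    parents = [parent]
                    # occasional second parent among shallower same-group terms
                    if depth > 0 and rng.random() < 0.15:
                        alt = members[int(rng.integers(len(members)))]
                        if alt != parent:
                            parents.append(alt)
                    terms[t] = {
                        "name": f"group{g} d{depth + 1} term {len(members)}",
                        "parents": parents,
                    }
                    members.append(t)
                    nxt.append(t)
            level = nxt
        group_terms[g] = members

    annotations: dict[str, set[str]] = {}
    truth_rows = []
    for g in range(cfg.n_groups):
        own = group_terms[g]
        other = [t for gg, ts in group_terms.items() if gg != g for t in ts]
        for j in range(cfg.proteins_per_group):
            pid = f"SIMPROT{g * cfg.proteins_per_group + j + 1:04d}"
            chosen: set[str] = set()
            while len(chosen) < cfg.terms_per_protein:
                pool = own if (not other or rng.random() >= cfg.noise_p) else other
                chosen.add(pool[int(rng.integers(len(pool)))])
            annotations[pid] = chosen
            truth_rows.append((pid, g))

    obo_lines = ["format-version: 1.2", f"ontology: sim-{ns}", ""]
    for term, info in terms.items():
        obo_lines += ["[Term]", f"id: {term}", f"name: {info['name']}",
                      f"namespace: {ns}"]
        for p in info["parents"]:
            obo_lines.append(f"is_a: {p} ! {terms[p]['name']}")
        obo_lines.append("")
    obo_text = "\n".join(obo_lines)

    gaf_lines = ["!gaf-version: 2.1"]
    for pid in sorted(annotations):
        for term in sorted(annotations[pid]):
            gaf_lines.append("\t".join([
                "SIM", pid, pid, "", term, "SIM:0000001", "IEA", "", aspect,
                pid, "", "protein", "taxon:9606", "20111108", "SIM", "", "",
            ]))
    gaf_text = "\n".join(gaf_lines) + "\n"

    truth = pd.DataFrame(truth_rows, columns=["protein_id", "group"])
    return GoCorpus(obo_text=obo_text, gaf_text=gaf_text, truth=truth,
                    group_terms=group_terms, annotations=annotations)


# ---------------------------------------------------------------------------
# C-terminal peptides
# ---------------------------------------------------------------------------

@dataclass
class TerminiSimConfig:
    """Conditions for planted-motif C-terminal peptide sets."""

    n_seqs: int = 100
    frac_class1: float = 0.3
    frac_cys: float = 0.15
    length: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.n_seqs < 1:
            raise ConfigurationError("n_seqs must be >= 1")
        if not 0 <= self.frac_class1 <= 1 or not 0 <= self.frac_cys <= 1:
            raise ConfigurationError("motif fractions must lie in [0, 1]")
        if self.frac_class1 + self.frac_cys > 1:
            raise ConfigurationError("frac_class1 + frac_cys must be <= 1")
        if self.length < 3:
            raise ConfigurationError("length must be >= 3")


def random_peptides(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Peptides drawn uniformly over the 20 standard amino acids."""
    idx = rng.integers(0, 20, size=(n, length))
    return ["".join(AMINO_ACIDS_20[i] for i in row) for row in idx]


def simulate_termini(cfg: TerminiSimConfig) -> tuple[str, pd.DataFrame]:
    """Generate C-terminal peptides with exact planted motif counts.

    Returns ``(fasta_text, truth)`` where truth has columns ``protein_id``,
    ``sequence`` and ``planted`` in {class1, cys_terminal, background}.
    ``floor(frac_class1 * n)`` sequences carry S/T at -2 and a hydrophobic
    residue at 0; ``floor(frac_cys * n)`` end in Cys; background sequences
    are rejection-sampled away from both planted motifs so the planted
    counts are exact.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_class1 = int(cfg.frac_class1 * cfg.n_seqs)
    n_cys = int(cfg.frac_cys * cfg.n_seqs)
    hydro = sorted(HYDROPHOBIC_0)

    records: list[tuple[str, str, str]] = []
    i = 0

    def fresh() -> list[str]:
        return list(random_peptides(1, cfg.length, rng)[0])

    for _ in range(n_class1):
        i += 1
        seq = fresh()
        seq[-3] = "ST"[int(rng.integers(2))]
        seq[-1] = hydro[int(rng.integers(len(hydro)))]
        records.append((f"T{i:05d}", "".join(seq), "class1"))
    for _ in range(n_cys):
        i += 1
        seq = fresh()
        seq[-1] = "C"
        records.append((f"T{i:05d}", "".join(seq), "cys_terminal"))
    for _ in range(cfg.n_seqs - n_class1 - n_cys):
        i += 1
        while True:
            seq = "".join(fresh())
            if seq[-1] == "C":
                continue
            if seq[-3] in "ST" and seq[-1] in HYDROPHOBIC_0:
                continue
            break
        records.append((f"T{i:05d}", seq, "background"))

    fasta = "".join(f">{pid}\n{seq}\n" for pid, seq, _lab in records)
    truth = pd.DataFrame(records, columns=["protein_id", "sequence", "planted"])
    return fasta, truth


def write_termini(fasta_text: str, truth: pd.DataFrame,
                  outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "termini.fasta"
    truth_path = outdir / "truth_motifs.tsv"
    fasta.write_text(fasta_text)
    truth.to_csv(truth_path, sep="\t", index=False)
    return fasta, truth_path
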