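"""Synthetic TGIRT-seq library generator with per-read ground truth.

Emulates the artifacts that make TGIRT-seq informative for tRNA fragment
analysis:

* Dicer cleavage of full-length molecules at configurable sites, with a
  per-site probability multiplier applied when the substrate 5' end is
  phospho-dimethylated (Pme2), modelling methylation-sensitive cuts.
* Reverse-transcription artifacts: misincorporation at m1A/m1G positions
  (T/G-dominated spectrum at m1A), premature stops at the m1G roadblock
  (the RT copies 3'->5', so a stop yields a 5'-truncated sense read),
  a non-templated T prepended to the sense read (non-templated A addition
  at the cDNA 3' end), and generic fall-off near the start of cDNA
  synthesis (a short 3'-end truncation of the sense read).
* Uniform substitution sequencing error applied after the RT layer.

Reads are emitted merged and in sense orientation (no paired ends, no
adapters). Quality strings are a constant placeholder since the analysis
never uses them. One top-level seed; each molecule draws from a
counter-derived substream, so truth tables are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .reference import (
    MIR4454_ID,
    TRNA_HIS_ID,
    PaddedReference,
    default_reference,
)

BASES = "ACGT"
CHEMISTRIES = ("OH", "P", "Pme1", "Pme2")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Molecule:
    """One RNA molecule: source entry, 5' chemistry, span on the source core."""

    source_id: str
    five_prime_chem: str
    core_span: tuple[int, int]
    is_five_prime_product: bool = False
    is_three_prime_product: bool = False

    def __post_init__(self) -> None:
        s, e = self.core_span
        if not (0 <= s < e):
            raise SimulationError(f"bad span {self.core_span}")
        if self.five_prime_chem not in CHEMISTRIES:
            raise SimulationError(f"unknown chemistry {self.five_prime_chem!r}")

    def length(self) -> int:
        return self.core_span[1] - self.core_span[0]


@dataclass(frozen=True)
class CutSite:
    cut_after_core_index: int
    base_probability: float
    #: multiplier applied to base_probability for 5'Pme2 substrates;
    #: <1 means the cut is inhibited by phospho-methylation.
    methyl_sensitivity: float = 1.0

    def effective_probability(self, chem: str) -> float:
        p = self.base_probability
        if chem == "Pme2":
            p *= self.methyl_sensitivity
        return p


@dataclass(frozen=True)
class CutModel:
    sites: tuple[CutSite, ...]

    def __post_init__(self) -> None:
        for s in self.sites:
            if not 0.0 <= s.base_probability <= 1.0:
                raise SimulationError("cut probability outside [0,1]")
            if not 0.0 <= s.methyl_sensitivity <= 1.0:
                raise SimulationError("methyl sensitivity outside [0,1]")

    def total_probability(self, chem: str) -> float:
        return sum(s.effective_probability(chem) for s in self.sites)


@dataclass(frozen=True)
class Misincorporation:
    rate: float
    #: probability of each read base given a misincorporation event
    spectrum: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.spectrum)
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("misincorporation spectrum does not sum to 1")


@dataclass(frozen=True)
class RtModel:
    """TGIRT artifact model; site maps are core indices on `applies_to`."""

    misincorporation: tuple[tuple[int, Misincorporation], ...] = ()
    premature_stop: tuple[tuple[int, float], ...] = ()
    nontemplated_5p_T_prob: float = 0.0
    terminal_truncation_prob: float = 0.0
    max_truncation_nt: int = 3
    applies_to: str = TRNA_HIS_ID


# Paper-calibrated default Dicer cut model for tRNA-His: two
# methylation-sensitive sites on the double-stranded side of the TPsiC arm
# (after core 54 and 57; the dominant 3' product is the 18-mer starting at
# the m1A base) and one insensitive minor site in the loop (after core 60).
# Total per-molecule cleavage probability 0.54 for a 5'P substrate.
DEFAULT_CUT_MODEL = CutModel(
    sites=(
        CutSite(54, 0.22, methyl_sensitivity=0.2),
        CutSite(57, 0.25, methyl_sensitivity=0.2),
        CutSite(60, 0.07, methyl_sensitivity=0.9),
    )
)

DEFAULT_RT_MODEL = RtModel(
    misincorporation=(
        (37, Misincorporation(0.08, (("T", 0.4), ("C", 0.3), ("A", 0.3)))),
        (58, Misincorporation(0.30, (("T", 0.6), ("G", 0.3), ("C", 0.1)))),
    ),
    premature_stop=((37, 0.25),),
    nontemplated_5p_T_prob=0.15,
    terminal_truncation_prob=0.05,
    max_truncation_nt=3,
    applies_to=TRNA_HIS_ID,
)

#: molecule species available to preset compositions: name -> (source entry,
#: span on the source core or None for full length)
SPECIES: dict[str, tuple[str, tuple[int, int] | None]] = {
    "trna_his": (TRNA_HIS_ID, None),
    "trna_his_3p18": (TRNA_HIS_ID, (58, 76)),
    "trna_his_3p21": (TRNA_HIS_ID, (55, 76)),
    "trna_his_3p26": (TRNA_HIS_ID, (50, 76)),
    "mir4454_decoy": (MIR4454_ID, None),
    "bg_snrna": ("bg-snRNA-like", None),
    "bg_hairpin": ("bg-hairpin-like", None),
    "bg_mirna": ("bg-mirna-like", None),
}


@dataclass(frozen=True)
class SimPreset:
    name: str
    n_molecules: int
    composition: tuple[tuple[str, float], ...]
    five_prime_chem: str = "P"
    cut_model: CutModel | None = None
    rt_model: RtModel = DEFAULT_RT_MODEL
    seq_error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.composition:
            raise SimulationError("empty composition")
        total = sum(p for _, p in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"composition sums to {total}, not 1")
        for name, _ in self.composition:
            if name not in SPECIES:
                raise SimulationError(f"unknown species {name!r}")


_BG_EVEN = (("bg_snrna", 0.40), ("bg_hairpin", 0.35), ("bg_mirna", 0.25))

PRESETS: dict[str, SimPreset] = {
    # in-vitro Dicer assay arms: a single synthetic tRNA-His substrate
    "mock": SimPreset("mock", 20000, (("trna_his", 1.0),), "P", None),
    "dicer_5p": SimPreset("dicer_5p", 20000, (("trna_his", 1.0),), "P", DEFAULT_CUT_MODEL),
    "dicer_5pme2": SimPreset(
        "dicer_5pme2", 20000, (("trna_his", 1.0),), "Pme2", DEFAULT_CUT_MODEL
    ),
    # pulldown characterization: IP vs control FLAG eluates
    "pulldown_control": SimPreset("pulldown_control", 10000, _BG_EVEN),
    "pulldown_b3df": SimPreset(
        "pulldown_b3df",
        10000,
        (
            ("trna_his", 0.45),
            ("trna_his_3p18", 0.20),
            ("bg_snrna", 0.14),
            ("bg_hairpin", 0.12),
            ("bg_mirna", 0.09),
        ),
    ),
    # cellular small-RNA libraries, knockdown vs scrambled control; the
    # knockdown doubles the 3'-fragment proportion
    "shNC": SimPreset(
        "shNC",
        10000,
        (
            ("trna_his", 0.25),
            ("trna_his_3p18", 0.01),
            ("bg_snrna", 0.30),
            ("bg_hairpin", 0.24),
            ("bg_mirna", 0.20),
        ),
    ),
    "shB3D": SimPreset(
        "shB3D",
        10000,
        (
            ("trna_his", 0.25),
            ("trna_his_3p18", 0.02),
            ("bg_snrna", 0.29),
            ("bg_hairpin", 0.24),
            ("bg_mirna", 0.20),
        ),
    ),
    # 50/50 tRNA-3'-fragment / annotated-miRNA-decoy mixture with
    # heterogeneous fragment 5' ends, for provenance classification
    "provenance_mix": SimPreset(
        "provenance_mix",
        10000,
        (
            ("trna_his_3p26", 0.075),
            ("trna_his_3p21", 0.15),
            ("trna_his_3p18", 0.275),
            ("mir4454_decoy", 0.5),
        ),
    ),
}


def get_preset(name: str, n_molecules: int | None = None, seed: int | None = None) -> SimPreset:
    if name not in PRESETS:
        raise SimulationError(f"unknown preset {name!r}; know {sorted(PRESETS)}")
    preset = PRESETS[name]
    changes: dict = {}
    if n_molecules is not None:
        changes["n_molecules"] = n_molecules
    if seed is not None:
        changes["seed"] = seed
    return replace(preset, **changes) if changes else preset


def _species_molecule(name: str, chem: str, ref: PaddedReference) -> Molecule:
    source_id, span = SPECIES[name]
    core_len = len(ref.core(source_id))
    if span is None:
        span = (0, core_len)
        return Molecule(source_id, chem, span)
    # pre-made fragments carry a cleavage-generated 5' monophosphate
    return Molecule(
        source_id,
        "P",
        span,
        is_three_prime_product=span[1] == core_len and span[0] > 0,
        is_five_prime_product=span[0] == 0 and span[1] < core_len,
    )


def simulate_pool(preset: SimPreset, ref: PaddedReference | None = None) -> list[Molecule]:
    """Draw the molecule pool for a preset; deterministic given its seed."""
    if ref is None:
        ref = default_reference()[0]
    rng = np.random.default_rng([int(preset.seed), 0])
    names = [n for n, _ in preset.composition]
    probs = np.array([p for _, p in preset.composition])
    picks = rng.choice(len(names), size=preset.n_molecules, p=probs)
    return [_species_molecule(names[k], preset.five_prime_chem, ref) for k in picks]


def apply_dicer(
    mol: Molecule, cuts: CutModel | None, rng: np.random.Generator
) -> list[Molecule]:
    """Cleave a full-length molecule at most once per the cut model.

    Site probabilities are multiplied by their methyl sensitivity for Pme2
    substrates. The site is drawn in descending-probability order (uniform
    tie-break on the cut index) from one uniform variate, so the marginal
    per-site probabilities are exact.
    """
    if cuts is None or not cuts.sites:
        return [mol]
    chem = mol.five_prime_chem
    order = sorted(
        cuts.sites, key=lambda s: (-s.effective_probability(chem), s.cut_after_core_index)
    )
    u = rng.random()
    acc = 0.0
    for site in order:
        acc += site.effective_probability(chem)
        if u < acc:
            c = site.cut_after_core_index
            s, e = mol.core_span
            if not (s <= c < e - 1):
                raise SimulationError(f"cut after {c} outside molecule span {mol.core_span}")
            five = Molecule(mol.source_id, chem, (s, c + 1), is_five_prime_product=True)
            three = Molecule(mol.source_id, "P", (c + 1, e), is_three_prime_product=True)
            return [five, three]
    return [mol]


@dataclass
class SimRead:
    """A sense-orientation read after the RT layer (pre sequencing error)."""

    sequence: str
    read_start: int
    read_end: int
    rt_stop_index: int | None = None
    misinc_positions: list[int] = field(default_factory=list)
    nontemplated_5p_T: bool = False


def reverse_transcribe(
    mol: Molecule, core: str, rt: RtModel, rng: np.random.Generator
) -> SimRead:
    """Copy a molecule 3'->5' and report the cDNA as a sense-strand read.

    A premature stop at core index i yields a sense read starting at i (the
    modified base is the last one copied); generic fall-off trims 1..k bases
    from the sense 3' end; misincorporation substitutes read bases at
    modified positions; the non-templated addition prepends one T.
    """
    start, end = mol.core_span
    stop_index: int | None = None
    if rt.applies_to == mol.source_id:
        # RT proceeds 3'->5': the highest-index roadblock is reached first
        for idx, p in sorted(rt.premature_stop, key=lambda t: -t[0]):
            if start < idx < end and rng.random() < p:
                stop_index = idx
                start = idx
                break
    if rt.terminal_truncation_prob > 0 and rng.random() < rt.terminal_truncation_prob:
        k = int(rng.integers(1, rt.max_truncation_nt + 1))
        end = max(start + 1, end - k)
    bases = list(core[start:end])
    misinc: list[int] = []
    if rt.applies_to == mol.source_id:
        for idx, model in rt.misincorporation:
            if start <= idx < end and rng.random() < model.rate:
                letters = [b for b, _ in model.spectrum]
                probs = [p for _, p in model.spectrum]
                bases[idx - start] = letters[int(rng.choice(len(letters), p=probs))]
                misinc.append(idx)
    nt5p = rng.random() < rt.nontemplated_5p_T_prob
    seq = ("T" if nt5p else "") + "".join(bases)
    return SimRead(seq, start, end, stop_index, misinc, nt5p)


def add_sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        cur = arr[i].decode()
        alts = [b for b in BASES if b != cur]
        arr[i] = alts[int(rng.integers(3))].encode()
    return arr.tobytes().decode()


TRUTH_COLUMNS = [
    "read_id",
    "source_id",
    "five_prime_chem",
    "mol_start",
    "mol_end",
    "read_start",
    "read_end",
    "cut_after",
    "rt_stop_index",
    "misinc_positions",
    "nontemplated_5p_T",
    "read_len",
]


def simulate_reads(
    preset: SimPreset, ref: PaddedReference | None = None
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Run the full generator: (read_id, sequence) pairs plus the truth table.

    Every molecule yields one read; a cleaved molecule yields one read per
    product, so reads out = molecules after cleavage.
    """
    if ref is None:
        ref = default_reference()[0]
    pool = simulate_pool(preset, ref)
    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    counter = 0
    for i, mol in enumerate(pool):
        rng = np.random.default_rng([int(preset.seed), 1, i])
        cut_products = (
            apply_dicer(mol, preset.cut_model, rng)
            if mol.core_span == (0, len(ref.core(mol.source_id)))
            else [mol]
        )
        cut_after = cut_products[0].core_span[1] - 1 if len(cut_products) == 2 else -1
        for product in cut_products:
            sim = reverse_transcribe(product, ref.core(product.source_id), preset.rt_model, rng)
            seq = add_sequencing_errors(sim.sequence, preset.seq_error_rate, rng)
            read_id = f"{preset.name}.{counter:07d}"
            counter += 1
            reads.append((read_id, seq))
            rows.append(
                {
                    "read_id": read_id,
                    "source_id": product.source_id,
                    "five_prime_chem": product.five_prime_chem,
                    "mol_start": product.core_span[0],
                    "mol_end": product.core_span[1],
                    "read_start": sim.read_start,
                    "read_end": sim.read_end,
                    "cut_after": cut_after,
                    "rt_stop_index": -1 if sim.rt_stop_index is None else sim.rt_stop_index,
                    "misinc_positions": ";".join(map(str, sim.misinc_positions)),
                    "nontemplated_5p_T": int(sim.nontemplated_5p_T),
                    "read_len": len(seq),
                }
            )
    return reads, pd.DataFrame(rows, columns=TRUTH_COLUMNS)


@dataclass(frozen=True)
class LibraryManifest:
    preset: str
    seed: int
    n_molecules: int
    n_reads: int
    fastq_sha256: str
    truth_sha256: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def emit_library(
    preset: SimPreset,
    out_fastq: str | os.PathLike,
    out_truth_tsv: str | os.PathLike,
    ref: PaddedReference | None = None,
    manifest_path: str | os.PathLike | None = None,
) -> LibraryManifest:
    """Write the FASTQ and truth TSV; byte-identical across runs per seed."""
    reads, truth = simulate_reads(preset, ref)
    try:
        with open(out_fastq, "w") as fh:
            for read_id, seq in reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        truth.to_csv(out_truth_tsv, sep="\t", index=False)
    except OSError as exc:  # I/O failures are distinct from simulation errors
        raise OSError(f"cannot write library output: {exc}") from exc
    manifest = LibraryManifest(
        preset=preset.name,
        seed=preset.seed,
        n_molecules=preset.n_molecules,
        n_reads=len(reads),
        fastq_sha256=_sha256(out_fastq),
        truth_sha256=_sha256(out_truth_tsv),
    )
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            fh.write(manifest.to_json() + "\n")
    return manifest


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Minimal 4-line FASTQ reader returning (read_id, sequence) pairs."""
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header.strip().lstrip("@").split()[0], seq))
    return reads
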