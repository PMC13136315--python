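"""End-to-end synthetic experiments.

Generates everything a barcoding analysis consumes — codebooks, simulated
molecules, electropherogram traces, and paired FASTQ reads with per-read
ground truth — so the whole pipeline is testable without any sequencing
data.  Two synthetic "species" stand in for a mixed human/mouse culture:
each species owns a pool of random transcript tags, and a configurable
fraction ``h`` of reads draw their tag from the partner species' pool,
emulating cross-species homology (the floor on any mixed-species
demultiplexing benchmark).

All randomness flows from the experiment seed; equal specs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as _seqio_write
from Bio.SeqRecord import SeqRecord

from .codebook import Codebook, Codeword, build_codebook, default_alphabet
from .demux import ReadLayout
from .electropherogram import Trace, synth_trace
from .ligation_model import (
    LigationError,
    LigationParams,
    MoleculeOutcome,
    length_histogram,
    simulate_molecules,
)
from .scheduler import Region

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "generate_experiment",
    "fixture_library",
]

# SmartSeq-like constant 5' tag on Read 1 (arbitrary fixed sequence)
DEFAULT_HANDLE = "ACACGACGCTCTTCCGATCT"
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ExperimentSpec:
    """Everything needed to synthesize one two-species barcoding run."""

    codebook: Codebook
    params: LigationParams
    region_species: dict[str, str]
    molecules_per_region: int = 10000
    read_error_rate: float = 0.001
    shared_fraction: float = 0.047
    pool_size: int = 500
    tag_bp: int = 60
    trace_sigma: float = 5.0
    trace_base_bp: float = 50.0
    handle: str = DEFAULT_HANDLE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.params.n_L != self.codebook.m:
            raise LigationError("params.n_L must equal codebook alphabet size")
        if self.params.R != self.codebook.n:
            raise LigationError("params.R must equal codebook round count")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise LigationError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.read_error_rate <= 1.0:
            raise LigationError("read_error_rate must be in [0, 1]")
        if self.molecules_per_region < 1:
            raise LigationError("molecules_per_region must be >= 1")
        missing = set(self.region_species) - set(self.codebook.assignment)
        if missing:
            raise LigationError(f"regions without codewords: {sorted(missing)}")
        if len(set(self.region_species.values())) != 2:
            raise LigationError("exactly two species are required")

    @property
    def layout(self) -> ReadLayout:
        letter_bp = len(self.codebook.letters[0])
        return ReadLayout(self.handle, self.codebook.n, letter_bp)


@dataclass
class ExperimentResult:
    """In-memory product of :func:`generate_experiment`."""

    spec: ExperimentSpec
    reads: list[tuple[str, str, str]]
    truth: pd.DataFrame
    traces: dict[str, Trace]
    species_index: dict[str, str]
    outcomes: dict[str, list[MoleculeOutcome]]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write R1/R2 FASTQ (gzip), truth TSV, traces, and provenance."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "r1": out_dir / "reads_R1.fastq.gz",
            "r2": out_dir / "reads_R2.fastq.gz",
            "truth": out_dir / "truth.tsv",
            "provenance": out_dir / "provenance.json",
        }
        import gzip

        def _records(index: int):
            for read_id, r1, r2 in self.reads:
                seq = (r1, r2)[index]
                rec = SeqRecord(Seq(seq), id=read_id, description="")
                rec.letter_annotations["phred_quality"] = [40] * len(seq)
                yield rec

        with gzip.open(paths["r1"], "wt") as fh:
            _seqio_write(_records(0), fh, "fastq")
        with gzip.open(paths["r2"], "wt") as fh:
            _seqio_write(_records(1), fh, "fastq")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        for region, trace in self.traces.items():
            p = out_dir / f"trace_{region}.csv"
            trace.to_csv(p)
            paths[f"trace_{region}"] = p
        spec = self.spec
        paths["provenance"].write_text(json.dumps({
            "seed": spec.seed,
            "d": spec.params.d,
            "c": spec.params.c,
            "n_L": spec.params.n_L,
            "R": spec.params.R,
            "molecules_per_region": spec.molecules_per_region,
            "read_error_rate": spec.read_error_rate,
            "shared_fraction": spec.shared_fraction,
            "pool_size": spec.pool_size,
            "tag_bp": spec.tag_bp,
            "regions": {r: str(cw) for r, cw in spec.codebook.assignment.items()},
            "region_species": spec.region_species,
        }, indent=2))
        return paths


def _random_pool(rng: np.random.Generator, size: int, tag_bp: int) -> list[str]:
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < size:
        tag = "".join(_BASES[rng.integers(0, 4, size=tag_bp)])
        if tag not in seen:
            seen.add(tag)
            pool.append(tag)
    return pool


def _mutate(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    """Apply iid per-base substitutions (always to a different base)."""
    if rate <= 0 or not seqs:
        return seqs
    arr = np.array([list(s) for s in seqs])
    hit = rng.random(arr.shape) < rate
    if hit.any():
        # shift by 1..3 positions in base order => always a different base
        base_idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=hit.sum())
        arr[hit] = _BASES[(base_idx + shift) % 4]
    return ["".join(row) for row in arr]


def generate_experiment(
    spec: ExperimentSpec, out_dir: Optional[str | Path] = None
) -> ExperimentResult:
    """Synthesize molecules, reads, and traces for every region in the spec.

    Per region: molecules are drawn from the on/off-target ligation process;
    each molecule yields one read pair whose Read 1 is the handle plus the
    molecule's *actual* barcode letters in reverse ligation order (padded
    with poly-T), and whose Read 2 is a transcript tag from the region's own
    species pool — or, with probability ``shared_fraction``, from the
    partner species' pool.  Region traces are synthesized from the empirical
    molecule-length histogram so downstream fits see the full stochastic
    path.
    """
    rng_pools, rng_mols, rng_tags, rng_err = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(spec.seed).spawn(4)
    ]
    species_names = sorted(set(spec.region_species.values()))
    pools = {name: _random_pool(rng_pools, spec.pool_size, spec.tag_bp)
             for name in species_names}
    species_index = {tag: name for name in species_names for tag in pools[name]}
    partner = {species_names[0]: species_names[1],
               species_names[1]: species_names[0]}

    layout = spec.layout
    letter_seq = {lid: let.sequence for lid, let in spec.codebook.letter_by_id.items()}
    read1_len = len(layout.handle) + layout.slot_width + 10
    regions = sorted(spec.region_species)
    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    traces: dict[str, Trace] = {}
    outcomes: dict[str, list[MoleculeOutcome]] = {}
    for region in regions:
        codeword = spec.codebook.assignment[region]
        seed_r = int(rng_mols.integers(0, 2 ** 31 - 1))
        mols = simulate_molecules(
            spec.params, codeword, spec.molecules_per_region, seed=seed_r
        )
        outcomes[region] = mols
        own = spec.region_species[region]
        foreign = rng_tags.random(len(mols)) < spec.shared_fraction
        tag_idx = rng_tags.integers(0, spec.pool_size, size=len(mols))
        r1_batch = []
        r2_batch = []
        for i, mol in enumerate(mols):
            rev = list(reversed(mol.barcode))  # last-ligated letter first
            body = "".join(letter_seq[lid] for lid in rev)
            r1 = (layout.handle + body)[:read1_len]
            r1 = r1 + "T" * (read1_len - len(r1))
            tag_species = partner[own] if foreign[i] else own
            r2 = pools[tag_species][tag_idx[i]]
            r1_batch.append(r1)
            r2_batch.append(r2)
            read_id = f"{region}_{i + 1:06d}"
            truth_rows.append(
                (read_id, region, str(codeword),
                 "".join(f"L{d}" for d in mol.barcode) or "-",
                 tag_species)
            )
        r1_batch = _mutate(r1_batch, spec.read_error_rate, rng_err)
        r2_batch = _mutate(r2_batch, spec.read_error_rate, rng_err)
        reads.extend(
            (f"{region}_{i + 1:06d}", r1_batch[i], r2_batch[i])
            for i in range(len(mols))
        )
        hist = length_histogram(mols)
        traces[region] = synth_trace(
            hist,
            base_bp=spec.trace_base_bp,
            letter_bp=float(layout.letter_bp),
            sigma=spec.trace_sigma,
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "region", "codeword", "molecule_barcode", "species"],
    )
    result = ExperimentResult(
        spec=spec,
        reads=reads,
        truth=truth,
        traces=traces,
        species_index=species_index,
        outcomes=outcomes,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def fixture_library() -> dict[str, dict]:
    """Small deterministic fixtures keyed by descriptive name.

    ``four_region_2x2``
        The canonical worked example: two letters, two rounds, four regions
        I..IV assigned L1L1, L1L2, L2L1, L2L2.
    ``two_letter_two_round``
        Observed barcode-length fractions from a four-region, two-letter,
        two-round experiment (2-letter 69.2%, 3-letter bound 3.5%).
    ``four_letter_three_round``
        Observed fractions from a 64-region, four-letter, three-round
        experiment (3-letter 58.3%, 4-letter 7.4%).
    ``two_region_mixed_species``
        A two-region, two-species experiment spec with 4.7% shared
        (homologous) transcript tags and perfect barcoding.
    """
    cb_2x2 = build_codebook(2, 2).assign(
        {"I": "L1L1", "II": "L1L2", "III": "L2L1", "IV": "L2L2"}
    )
    letters4 = default_alphabet(4)
    cb_mixed = Codebook(
        letters4,
        2,
        [Codeword((1, 3)), Codeword((2, 4))],
        {"top": Codeword((1, 3)), "bottom": Codeword((2, 4))},
    )
    mixed_spec = ExperimentSpec(
        codebook=cb_mixed,
        params=LigationParams(d=1.0, c=0.0, n_L=4, R=2),
        region_species={"top": "speciesA", "bottom": "speciesB"},
        molecules_per_region=10000,
        read_error_rate=0.0,
        shared_fraction=0.047,
        seed=0,
    )
    return {
        "four_region_2x2": {
            "codebook": cb_2x2,
            "regions": [Region(r) for r in ("I", "II", "III", "IV")],
        },
        "two_letter_two_round": {
            "observed_fractions": {1: 0.273, 2: 0.692, 3: 0.035},
            "inversion_lengths": (2, 3),
            "n_L": 2,
            "R": 2,
        },
        "four_letter_three_round": {
            "observed_fractions": {3: 0.583, 4: 0.074},
            "inversion_lengths": (3, 4),
            "n_L": 4,
            "R": 3,
        },
        "two_region_mixed_species": {"spec": mixed_spec},
    }
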