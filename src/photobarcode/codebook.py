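"""Combinatorial letter-ligation codebooks.

A spatial barcode is a word over an alphabet of ``m`` short DNA *letters*
built over ``n`` ligation rounds — one letter appended per round — so that
``m**n`` distinct codes can be written in only ``m * n`` ligation steps
(regions that receive the same letter in the same round are illuminated
together).  This module holds the static side of that design: letter
alphabets, codeword enumeration, repeat-code expansion for error robustness,
splint pools that template each (incoming, prior) letter junction, and the
simple efficiency arithmetic that governs how many molecules carry a
full-length barcode.

Letter ids are 1-based (``L1``..``Lm``) and digit 1 of a codeword is the
letter ligated in the earliest round.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq
from Bio.SeqIO import write as _seqio_write
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodebookError",
    "Letter",
    "Codeword",
    "Codebook",
    "Splint",
    "default_alphabet",
    "build_codebook",
    "expand_repeat_code",
    "effective_letter_efficiency",
    "full_length_fraction",
    "per_round_efficiency_from_fraction",
    "generate_splint_pool",
    "min_hamming_distance",
    "validate_letter_chemistry",
]

_DNA = frozenset("ACGT")

# splint geometry: complementary to the 3'-terminal 5-mer of the incoming
# letter plus the 5'-terminal 10-mer of the prior letter
SPLINT_INCOMING_BASES = 5
SPLINT_PRIOR_BASES = 10


class CodebookError(ValueError):
    """Invalid codebook, letter, or efficiency parameters."""


@dataclass(frozen=True)
class Letter:
    """One barcode letter: a short oligonucleotide ligated in a single step.

    Parameters
    ----------
    id
        1-based letter identifier (``L1`` .. ``Lm``).
    sequence
        The letter's nucleotide sequence, 5'→3'.  Must be at least 15 nt
        (long enough to carry both splint-binding segments) over {A,C,G,T}.
    detect_tag
        Optional sub-sequence read out by a fluorescent hybridization probe,
        located 5' of the photocleavable spacer.
    """

    id: int
    sequence: str
    detect_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id < 1:
            raise CodebookError(f"letter id must be >= 1, got {self.id}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 15:
            raise CodebookError(
                f"letter L{self.id}: sequence length {len(seq)} < 15"
            )
        bad = set(seq) - _DNA
        if bad:
            raise CodebookError(
                f"letter L{self.id}: non-ACGT characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def validate_letter_chemistry(letter: Letter) -> list[str]:
    """Check ligation-friendliness heuristics; returns warning messages.

    Letters ligate most efficiently when they have at least 40% GC content
    and no G or C at either terminus.  Violations are reported (and warned)
    rather than raised, so arbitrary alphabets remain usable.
    """
    msgs = []
    seq = letter.sequence
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if gc < 0.40:
        msgs.append(f"letter L{letter.id}: GC content {gc:.0%} < 40%")
    if seq[0] in "GC" or seq[-1] in "GC":
        msgs.append(f"letter L{letter.id}: terminal G/C base")
    for m in msgs:
        warnings.warn(m, stacklevel=2)
    return msgs


@dataclass(frozen=True)
class Codeword:
    """An ordered tuple of letter ids; digit 1 = earliest ligation round."""

    digits: tuple[int, ...]

    def __post_init__(self) -> None:
        digits = tuple(int(d) for d in self.digits)
        object.__setattr__(self, "digits", digits)
        if not digits:
            raise CodebookError("codeword must have at least one digit")
        if any(d < 1 for d in digits):
            raise CodebookError(f"codeword digits must be >= 1: {digits}")

    def __len__(self) -> int:
        return len(self.digits)

    def __str__(self) -> str:
        return "".join(f"L{d}" for d in self.digits)

    @property
    def compact(self) -> str:
        """Digit-string form, e.g. ``'124'`` — only unambiguous for ids <= 9."""
        if any(d > 9 for d in self.digits):
            raise CodebookError("compact form requires letter ids <= 9")
        return "".join(str(d) for d in self.digits)

    @classmethod
    def parse(cls, text: str) -> "Codeword":
        """Parse ``'L1L2L4'`` or the compact digit string ``'124'``."""
        text = text.strip()
        if text.upper().startswith("L"):
            parts = [p for p in text.upper().split("L") if p]
            return cls(tuple(int(p) for p in parts))
        return cls(tuple(int(ch) for ch in text))

    def hamming(self, other: "Codeword") -> int:
        if len(self) != len(other):
            raise CodebookError("Hamming distance requires equal lengths")
        return sum(a != b for a, b in zip(self.digits, other.digits))


@dataclass(frozen=True)
class Splint:
    """A 15-nt ligation template spanning an (incoming, prior) letter junction.

    The splint is the exact reverse complement of the incoming letter's
    3'-terminal 5-mer followed by the prior letter's 5'-terminal 10-mer,
    and is named ``splint{incoming}{prior}`` (incoming letter id first).
    """

    name: str
    incoming_id: int
    prior_id: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != SPLINT_INCOMING_BASES + SPLINT_PRIOR_BASES:
            raise CodebookError(
                f"splint {self.name}: length {len(self.sequence)} != 15"
            )


@dataclass
class Codebook:
    """An alphabet of letters plus the codewords assigned to spatial regions.

    Attributes
    ----------
    letters
        The alphabet, ids 1..m, uniform sequence length, pairwise distinct.
    n
        Number of ligation rounds (codeword length).
    codewords
        The available codewords (each of length ``n``), pairwise distinct.
    assignment
        Mapping region id → codeword.  Injective: two regions never share a
        codeword, which is what makes demultiplexing well defined.
    """

    letters: list[Letter]
    n: int
    codewords: list[Codeword]
    assignment: dict[str, Codeword] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.letters:
            raise CodebookError("alphabet must contain at least one letter")
        ids = [let.id for let in self.letters]
        if len(set(ids)) != len(ids):
            raise CodebookError("duplicate letter ids")
        lengths = {len(let) for let in self.letters}
        if len(lengths) != 1:
            raise CodebookError("letter sequences must have uniform length")
        seqs = {let.sequence for let in self.letters}
        if len(seqs) != len(self.letters):
            raise CodebookError("letter sequences must be pairwise distinct")
        if self.n < 1:
            raise CodebookError(f"rounds n must be >= 1, got {self.n}")
        id_set = set(ids)
        seen: set[tuple[int, ...]] = set()
        for cw in self.codewords:
            if len(cw) != self.n:
                raise CodebookError(f"codeword {cw} has length != n={self.n}")
            if not set(cw.digits) <= id_set:
                raise CodebookError(f"codeword {cw} uses letters outside alphabet")
            if cw.digits in seen:
                raise CodebookError(f"duplicate codeword {cw}")
            seen.add(cw.digits)
        assigned = [cw.digits for cw in self.assignment.values()]
        if len(set(assigned)) != len(assigned):
            raise CodebookError("assignment is not injective on codewords")
        for region, cw in self.assignment.items():
            if cw.digits not in seen:
                raise CodebookError(
                    f"region {region!r} assigned codeword {cw} not in codebook"
                )

    @property
    def m(self) -> int:
        return len(self.letters)

    @property
    def letter_by_id(self) -> dict[int, Letter]:
        return {let.id: let for let in self.letters}

    def assign(self, mapping: Mapping[str, Codeword | str]) -> "Codebook":
        """Return a copy with regions assigned to codewords."""
        parsed = {
            rid: cw if isinstance(cw, Codeword) else Codeword.parse(cw)
            for rid, cw in mapping.items()
        }
        return Codebook(self.letters, self.n, list(self.codewords), parsed)

    def with_full_assignment(self, prefix: str = "region_") -> "Codebook":
        """Assign every codeword to a generated region id, in codeword order."""
        width = len(str(len(self.codewords)))
        mapping = {
            f"{prefix}{i + 1:0{width}d}": cw
            for i, cw in enumerate(self.codewords)
        }
        return Codebook(self.letters, self.n, list(self.codewords), mapping)

    def repeat_expand(self, r: int) -> "Codebook":
        """Repeat-code expansion: every digit ligated ``r`` times in a row.

        A digit of the original codeword is decodable as long as at least one
        of its ``r`` repeats survives, which lifts a per-letter efficiency
        ``p`` to ``1 - (1-p)**r``.
        """
        if r < 1:
            raise CodebookError(f"repeat count must be >= 1, got {r}")
        codewords = [expand_repeat_code(cw, r) for cw in self.codewords]
        assignment = {
            rid: expand_repeat_code(cw, r) for rid, cw in self.assignment.items()
        }
        return Codebook(self.letters, self.n * r, codewords, assignment)

    # ------------------------------------------------------------------ I/O

    def to_dict(self) -> dict:
        return {
            "rounds": self.n,
            "letters": [
                {"id": let.id, "sequence": let.sequence,
                 **({"detect_tag": let.detect_tag} if let.detect_tag else {})}
                for let in self.letters
            ],
            "codewords": [str(cw) for cw in self.codewords],
            "assignment": {rid: str(cw) for rid, cw in self.assignment.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        letters = [
            Letter(int(x["id"]), x["sequence"], x.get("detect_tag"))
            for x in d["letters"]
        ]
        codewords = [Codeword.parse(s) for s in d["codewords"]]
        assignment = {
            rid: Codeword.parse(s) for rid, s in d.get("assignment", {}).items()
        }
        return cls(letters, int(d["rounds"]), codewords, assignment)

    def save(self, path: str | Path) -> None:
        """Write YAML (``.yaml``/``.yml``) or JSON (``.json``) by extension."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def default_alphabet(m: int, length: int = 20, seed: int = 20) -> list[Letter]:
    """Generate a deterministic synthetic alphabet of ``m`` letters.

    Sequences are drawn to satisfy the ligation heuristics (>= 40% GC, A/T
    termini) and to be mutually well separated (pairwise Hamming distance
    >= 8 at the default length), so mismatch-tolerant demultiplexing remains
    unambiguous.  The same ``(m, length, seed)`` always yields the same
    alphabet.
    """
    if m < 1:
        raise CodebookError(f"alphabet size must be >= 1, got {m}")
    if length < 15:
        raise CodebookError(f"letter length must be >= 15, got {length}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    min_sep = max(1, length * 2 // 5)
    letters: list[Letter] = []
    attempts = 0
    while len(letters) < m:
        attempts += 1
        if attempts > 10000 * m:
            raise CodebookError("failed to generate a separated alphabet")
        arr = rng.integers(0, 4, size=length)
        seq = "".join(bases[arr])
        gc = (seq.count("G") + seq.count("C")) / length
        if gc < 0.40 or seq[0] in "GC" or seq[-1] in "GC":
            continue
        if any(
            sum(a != b for a, b in zip(seq, let.sequence)) < min_sep
            for let in letters
        ):
            continue
        letters.append(Letter(len(letters) + 1, seq))
    return letters


def build_codebook(
    m: int,
    n: int,
    letters: Optional[Sequence[Letter]] = None,
    region_ids: Optional[Sequence[str]] = None,
) -> Codebook:
    """Enumerate the complete ``m**n`` codebook in lexicographic digit order.

    Parameters
    ----------
    m, n
        Alphabet size and number of ligation rounds; both >= 1.
    letters
        Optional explicit alphabet; must contain exactly ``m`` letters.
        When omitted a deterministic synthetic alphabet is generated.
    region_ids
        Optional region names assigned to the first ``len(region_ids)``
        codewords in enumeration order.
    """
    if m < 1 or n < 1:
        raise CodebookError(f"m and n must be >= 1, got m={m}, n={n}")
    if letters is None:
        letters = default_alphabet(m)
    elif len(letters) != m:
        raise CodebookError(f"expected {m} letters, got {len(letters)}")
    ids = sorted(let.id for let in letters)
    codewords = [Codeword(digits) for digits in itertools.product(ids, repeat=n)]
    cb = Codebook(list(letters), n, codewords)
    if region_ids is not None:
        if len(region_ids) > len(codewords):
            raise CodebookError("more region ids than codewords")
        cb = cb.assign(dict(zip(region_ids, codewords)))
    return cb


def expand_repeat_code(codeword: Codeword, r: int) -> Codeword:
    """Duplicate each digit ``r`` times in place (``L1L2`` → ``L1L1L2L2``)."""
    if r < 1:
        raise CodebookError(f"repeat count must be >= 1, got {r}")
    return Codeword(tuple(d for d in codeword.digits for _ in range(r)))


def effective_letter_efficiency(p: float, r: int) -> float:
    """Per-digit success probability under an ``r``-repeat code.

    A digit is recovered if at least one of its ``r`` repeated ligations
    succeeds: ``1 - (1-p)**r``.  With ``p = 0.9`` and ``r = 2`` this lifts
    the per-letter efficiency from 90% to 99%.
    """
    if not 0.0 <= p <= 1.0:
        raise CodebookError(f"probability p must be in [0, 1], got {p}")
    if r < 1:
        raise CodebookError(f"repeat count must be >= 1, got {r}")
    return 1.0 - (1.0 - p) ** r


def full_length_fraction(p: float, n: int) -> float:
    """Fraction of molecules carrying all ``n`` letters: ``p**n``.

    Assumes each round's photocleavage + ligation succeeds independently
    with probability ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise CodebookError(f"probability p must be in [0, 1], got {p}")
    if n < 1:
        raise CodebookError(f"rounds n must be >= 1, got {n}")
    return p ** n


def per_round_efficiency_from_fraction(f: float, n: int) -> float:
    """Invert ``f = p**n`` for the per-round efficiency ``p = f**(1/n)``."""
    if not 0.0 <= f <= 1.0:
        raise CodebookError(f"fraction f must be in [0, 1], got {f}")
    if n < 1:
        raise CodebookError(f"rounds n must be >= 1, got {n}")
    return f ** (1.0 / n)


def generate_splint_pool(letters: Sequence[Letter]) -> list[Splint]:
    """One splint per ordered (incoming, prior) letter pair — ``m**2`` total.

    ``splint{i}{j}`` templates the ligation of incoming letter ``Li`` onto a
    barcode ending in ``Lj``; its sequence is the reverse complement of
    (``Li``'s 3'-terminal 5-mer + ``Lj``'s 5'-terminal 10-mer).
    """
    need = max(SPLINT_INCOMING_BASES, SPLINT_PRIOR_BASES)
    for let in letters:
        if len(let) < need:
            raise CodebookError(
                f"letter L{let.id} shorter than splint segments ({need} nt)"
            )
    pool = []
    for incoming in letters:
        for prior in letters:
            target = (
                incoming.sequence[-SPLINT_INCOMING_BASES:]
                + prior.sequence[:SPLINT_PRIOR_BASES]
            )
            pool.append(
                Splint(
                    name=f"splint{incoming.id}{prior.id}",
                    incoming_id=incoming.id,
                    prior_id=prior.id,
                    sequence=str(Seq(target).reverse_complement()),
                )
            )
    return pool


def min_hamming_distance(codebook: Codebook) -> int:
    """Minimum pairwise Hamming distance over the codebook's codewords."""
    words = codebook.codewords
    if len(words) < 2:
        raise CodebookError("need >= 2 codewords for a minimum distance")
    arr = np.array([cw.digits for cw in words])
    best = arr.shape[1]
    for i in range(len(arr) - 1):
        d = (arr[i + 1:] != arr[i]).sum(axis=1).min()
        if d < best:
            best = int(d)
            if best == 1:  # cannot go lower for distinct codewords
                break
    return best


def export_fasta(
    items: Iterable[Letter | Splint], path: str | Path
) -> int:
    """Write letters or splints as FASTA (id = ``L{i}`` or splint name)."""
    records = []
    for item in items:
        if isinstance(item, Letter):
            records.append(SeqRecord(Seq(item.sequence), id=f"L{item.id}", description=""))
        else:
            records.append(SeqRecord(Seq(item.sequence), id=item.name, description=""))
    return _seqio_write(records, str(path), "fasta")
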