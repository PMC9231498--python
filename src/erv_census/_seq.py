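"""Small nucleotide-sequence helpers shared across modules.

Sequences are plain uppercase ACGT strings throughout; numpy uint8 views are
used internally where per-site operations need to be vectorised.
"""

from __future__ import annotations

import math

import numpy as np

DNA = "ACGT"
_DNA_BYTES = np.frombuffer(DNA.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random ACGT string of length ``n``."""
    return bytes(_DNA_BYTES[rng.integers(0, 4, size=n)]).decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def hamming_fraction(a: str, b: str) -> float:
    """Mismatch fraction between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming_fraction requires equal lengths")
    if not a:
        return 0.0
    return float(np.mean(seq_to_array(a) != seq_to_array(b)))


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping dinucleotide composition.

    Used as a low-complexity filter: homopolymers score 0, a dinucleotide
    repeat scores 1 bit, random sequence approaches 4 bits.
    """
    if len(seq) < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        counts[d] = counts.get(d, 0) + 1
    total = len(seq) - 1
    ent = 0.0
    for c in counts.values():
        p = c / total
        ent -= p * math.log2(p)
    return ent


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str], description: str = "") -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            header = f">{name}" + (f" {description}" if description else "")
            fh.write(header + "\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
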