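"""DNA 2-bit encoding and the k-mer hypercube.

The four nucleotides form a 4-symbol alphabet encoded in two bits each
(T=00, C=01, A=10, G=11, the convention of the .2bit format family).  A
2-mer therefore maps to a 4-bit label, and the 16 labels are the vertices
of a 4-dimensional hypercube whose edges connect labels at Hamming
distance 1.  This module owns the letter/bit maps, the assembly and
parsing of 11-character register initialization strings
(aux | coin | node | theta), hypercube construction and FASTA k-mer
counting.
"""

from __future__ import annotations

import logging
from typing import Dict, Set, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: fixed 2-bit nucleotide code
LETTER_TO_BITS = {"T": "00", "C": "01", "A": "10", "G": "11"}
BITS_TO_LETTER = {v: k for k, v in LETTER_TO_BITS.items()}

#: (aux, coin, node, theta) widths of the 11-qubit register
REGISTER_WIDTHS = (1, 2, 4, 4)


def _check_binary(s: str, width: int, what: str) -> None:
    if len(s) != width:
        raise ValueError(f"{what} must have length {width}, got {len(s)}")
    for i, ch in enumerate(s):
        if ch not in "01":
            raise ValueError(
                f"non-binary character {ch!r} at position {i} of {what}"
            )


def encode_kmer(kmer: str) -> str:
    """Encode a DNA k-mer into its 2-bit node label, left to right.

    >>> encode_kmer("CA")
    '0110'
    """
    bits = []
    for i, letter in enumerate(kmer.upper()):
        code = LETTER_TO_BITS.get(letter)
        if code is None:
            raise ValueError(
                f"invalid nucleotide {letter!r} at position {i} "
                f"(expected one of T, C, A, G)"
            )
        bits.append(code)
    return "".join(bits)


def decode_node(bits: str) -> str:
    """Exact inverse of :func:`encode_kmer`: 2k-bit label back to a k-mer."""
    if len(bits) % 2 != 0:
        raise ValueError(f"node label must have even length, got {len(bits)}")
    _check_binary(bits, len(bits), "node label")
    return "".join(BITS_TO_LETTER[bits[i : i + 2]] for i in range(0, len(bits), 2))


def build_init_string(aux: str, coin: str, node: str, theta: str) -> str:
    """Concatenate register values into the 11-character initialization string.

    Order is aux | coin | node | theta, so theta occupies the rightmost
    characters (qubits 0-3 under the right-to-left loading convention).
    """
    aux = str(aux)
    _check_binary(aux, 1, "aux")
    _check_binary(coin, 2, "coin")
    _check_binary(node, 4, "node")
    _check_binary(theta, 4, "theta")
    return aux + coin + node + theta


def parse_init_string(s: str) -> Tuple[str, str, str, str]:
    """Split an 11-character initialization string into
    (aux, coin, node, theta)."""
    _check_binary(s, 11, "initialization string")
    return s[0], s[1:3], s[3:7], s[7:11]


def hypercube_edges(n_bits: int) -> Set[Tuple[str, str]]:
    """All unordered vertex pairs at Hamming distance 1 on the n-bit
    hypercube (``2**(n-1) * n`` edges)."""
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    edges = set()
    for v in range(2**n_bits):
        for i in range(n_bits):
            u = v ^ (1 << i)
            if u > v:
                edges.add(
                    (format(v, f"0{n_bits}b"), format(u, f"0{n_bits}b"))
                )
    return edges


def fasta_kmer_census(path, k: int = 2) -> Dict[str, int]:
    """Sliding-window k-mer counts over every record of a FASTA file.

    Lowercase letters are uppercased; windows containing characters outside
    {T, C, A, G} (e.g. N) are skipped with a logged warning.  Node labels
    for each k-mer are available via :func:`encode_kmer`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Dict[str, int] = {}
    n_records = 0
    skipped = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(record.seq).upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if any(ch not in LETTER_TO_BITS for ch in window):
                skipped += 1
                continue
            counts[window] = counts.get(window, 0) + 1
    if n_records == 0:
        raise ValueError(f"no FASTA records found in {path}")
    if skipped:
        logger.warning(
            "skipped %d k-mer windows containing non-ACGT characters", skipped
        )
    return counts
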