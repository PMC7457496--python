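"""Shared exact k-mer seeding helpers (dict-based, desk-scale)."""

from __future__ import annotations

from collections import defaultdict

from .seqio import revcomp


def kmer_index(residues: str, k: int) -> dict[str, list[int]]:
    """Map every k-mer of ``residues`` to its (possibly multiple) start offsets."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(residues) - k + 1):
        index[residues[i : i + k]].append(i)
    return index


def kmer_set(residues: str, k: int) -> set[str]:
    return {residues[i : i + k] for i in range(len(residues) - k + 1)}


def shared_kmer_fraction(query: str, subject_kmers: set[str], k: int) -> float:
    """Fraction of the query's k-mers present in a precomputed subject set.

    A cheap orientation/identity proxy: ~1.0 for near-identical sequences,
    ~0.0 for unrelated ones; degrades smoothly with divergence.
    """
    total = len(query) - k + 1
    if total <= 0:
        return 0.0
    hits = sum(1 for i in range(total) if query[i : i + k] in subject_kmers)
    return hits / total


def orientation_identity(query: str, subject: str, k: int = 31) -> tuple[float, float]:
    """(forward, reverse-complement) shared k-mer fractions of query vs subject."""
    subject_kmers = kmer_set(subject, k)
    return (
        shared_kmer_fraction(query, subject_kmers, k),
        shared_kmer_fraction(revcomp(query), subject_kmers, k),
    )
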