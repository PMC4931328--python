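"""Exhaustive unique-alignment scan shared by the miCLIP and bisulfite callers.

Emulates best-stratum unique mapping with at most one mismatch: all
positions of all contigs are scanned on both strands; a read is accepted
iff the best non-empty mismatch stratum (0 = exact, 1 = one mismatch)
contains exactly one hit.  Genomes here are toy-scale, so a vectorised
sliding-window scan is both exact and fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .refmodel import Genome, revcomp


@dataclass(frozen=True)
class Hit:
    contig: str
    strand: str
    left: int  # leftmost 0-based genomic coordinate of the aligned span
    length: int
    mismatches: int

    @property
    def first_aligned_pos(self) -> int:
        """0-based genomic coordinate of the read's 5'-most base, transcript sense."""
        return self.left if self.strand == "+" else self.left + self.length - 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan(query: np.ndarray, contig_arr: np.ndarray, max_mismatch: int):
    """(position, mismatches) of every placement with <= max_mismatch."""
    L = len(query)
    if L == 0 or L > len(contig_arr):
        return []
    windows = sliding_window_view(contig_arr, L)
    mism = (windows != query).sum(axis=1)
    pos = np.nonzero(mism <= max_mismatch)[0]
    return [(int(p), int(mism[p])) for p in pos]


def scan_hits(
    seq: str,
    genome: Genome,
    max_mismatch: int = 1,
    transform: str | None = None,
) -> list[Hit]:
    """All hits of ``seq`` on both strands of ``genome``.

    With ``transform='CT'`` the scan is directional-bisulfite aware: the
    read and the forward genome are C->T collapsed for forward hits, and
    the reverse-complemented read and the G->A collapsed genome for
    reverse hits (a transcript-strand C on '-' is a forward-strand G).
    """
    hits: list[Hit] = []
    if transform is None:
        fw_query = _encode(seq)
        rv_query = _encode(revcomp(seq))
        fw_contigs = rv_contigs = genome.encoded(None)
    elif transform == "CT":
        fw_query = _encode(seq.replace("C", "T"))
        rv_query = _encode(revcomp(seq).replace("G", "A"))
        fw_contigs = genome.encoded("CT")
        rv_contigs = genome.encoded("GA")
    else:
        raise ValueError(f"unknown transform {transform!r}")
    L = len(seq)
    for name, arr in fw_contigs.items():
        for p, m in _scan(fw_query, arr, max_mismatch):
            hits.append(Hit(name, "+", p, L, m))
    for name, arr in rv_contigs.items():
        for p, m in _scan(rv_query, arr, max_mismatch):
            hits.append(Hit(name, "-", p, L, m))
    return hits


def best_stratum_unique(hits: list[Hit]):
    """(hit, category): the unique best-stratum hit, or None with a reason.

    category is 'unique', 'multimapper' or 'unmapped'.
    """
    if not hits:
        return None, "unmapped"
    best = min(h.mismatches for h in hits)
    stratum = [h for h in hits if h.mismatches == best]
    if len(stratum) == 1:
        return stratum[0], "unique"
    return None, "multimapper"
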