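"""Conversion calling for bisulfite-family libraries and m5C/f5C deconvolution.

Plain bisulfite (BS) deaminates unmodified C and f5C to U (read T) while
m5C and hm5C resist, so the BS non-conversion level at a site estimates
P(m5C) + P(hm5C).  RedBS (NaBH4 reduction of f5C to hm5C) and fCAB
(O-ethylhydroxylamine protection of f5C) additionally shield f5C, so
their levels estimate P(m5C) + P(hm5C) + P(f5C).  The deconvolution is a
clamped point-estimate difference:

    est_m5c_hm5c = level_BS
    est_f5c_red  = clamp(level_RedBS - level_BS, 0, 1)
    est_f5c_fcab = clamp(level_fCAB  - level_BS, 0, 1)

with binomial standard errors, and optional division by the reduction /
protection efficiencies rho and pi.  hm5C is never estimated separately:
it rides inside the m5C(+hm5C) bundle, which is all bisulfite chemistry
can resolve.

Reads are aligned directionally against an in-silico C->T collapsed
reference (transcript strand only) reusing the best-stratum unique scan,
then original bases are restored for calling.  Levels are reported for
every reference cytosine with coverage >= 5 by default, with and without
collapsing of identical (start, sequence) PCR duplicates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import _align
from .refmodel import ReferenceBundle

MIN_COVERAGE = 5


@dataclass(frozen=True)
class BsAlignment:
    contig: str
    strand: str
    left: int  # leftmost 0-based genomic coordinate
    read: str  # original (unconverted-alphabet) read sequence


def align_bisulfite(read: str, genome, max_mismatch: int = 1) -> BsAlignment | None:
    """Unique directional bisulfite alignment of one read.

    The read is C->T collapsed and scanned against the C->T collapsed
    forward genome ('+' transcripts) and, reverse-complemented, against
    the G->A collapsed genome ('-' transcripts); best-stratum uniqueness
    as in the miCLIP aligner.
    """
    hits = _align.scan_hits(read, genome, max_mismatch, transform="CT")
    hit, _ = _align.best_stratum_unique(hits)
    if hit is None:
        return None
    return BsAlignment(hit.contig, hit.strand, hit.left, read)


def align_library(fastq_path, genome, max_mismatch: int = 1, counters: Counter | None = None):
    """Align a whole FASTQ; returns the list of unique BsAlignments."""
    if counters is None:
        counters = Counter()
    cache: dict[str, BsAlignment | None] = {}
    out: list[BsAlignment] = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        counters["reads"] += 1
        seq = str(rec.seq)
        if seq in cache:
            aln = cache[seq]
        else:
            aln = align_bisulfite(seq, genome, max_mismatch)
            cache[seq] = aln
        if aln is None:
            counters["not_unique"] += 1
        else:
            counters["aligned"] += 1
            out.append(aln)
    return out


def _read_base_at(aln: BsAlignment, pos: int) -> str | None:
    """Transcript-sense read base covering 0-based genomic ``pos``."""
    if not (aln.left <= pos < aln.left + len(aln.read)):
        return None
    if aln.strand == "+":
        return aln.read[pos - aln.left]
    # read stored transcript-sense; forward coordinate maps from the 3' end
    return aln.read[aln.left + len(aln.read) - 1 - pos]


def _dedup(alignments: list[BsAlignment]) -> list[BsAlignment]:
    seen = set()
    out = []
    for aln in alignments:
        key = (aln.contig, aln.strand, aln.left, aln.read)
        if key not in seen:
            seen.add(key)
            out.append(aln)
    return out


def _gene_c_positions(bundle: ReferenceBundle, gene) -> list[tuple[int, int]]:
    """(seq_index, genomic 0-based pos) of every transcript-strand C."""
    seq = bundle.transcript_sequence(gene.gene_id)
    out = []
    for idx, base in enumerate(seq):
        if base == "C":
            pos1 = (
                gene.start + idx + 1 if gene.strand == "+" else gene.end - idx
            )
            out.append((idx, pos1 - 1))
    return out


def pileup(
    alignments: list[BsAlignment],
    bundle: ReferenceBundle,
    chemistry: str,
    dedup_mode: str = "without",
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cytosine conversion pileup over annotated genes.

    One row per transcript-strand reference C with columns coverage,
    n_unconverted (read C), n_converted (read T) and n_other.
    ``dedup_mode='with'`` collapses identical (start, sequence) pairs
    before counting, the toggle used to compile levels both ways.
    """
    if dedup_mode not in ("with", "without"):
        raise ValueError("dedup_mode must be 'with' or 'without'")
    if dedup_mode == "with":
        alignments = _dedup(alignments)
    gene_list = (
        bundle.annotations
        if genes is None
        else [bundle.gene(g) for g in genes]
    )
    by_gene: dict[str, list[BsAlignment]] = {g.gene_id: [] for g in gene_list}
    for aln in alignments:
        for g in gene_list:
            if (
                aln.contig == g.contig
                and aln.strand == g.strand
                and aln.left < g.end
                and aln.left + len(aln.read) > g.start
            ):
                by_gene[g.gene_id].append(aln)
    rows = []
    for g in gene_list:
        for idx, pos in _gene_c_positions(bundle, g):
            n_unc = n_conv = n_other = 0
            for aln in by_gene[g.gene_id]:
                base = _read_base_at(aln, pos)
                if base is None:
                    continue
                if base == "C":
                    n_unc += 1
                elif base == "T":
                    n_conv += 1
                else:
                    n_other += 1
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "seq_index": idx,
                    "position": pos + 1,
                    "coverage": n_unc + n_conv + n_other,
                    "n_unconverted": n_unc,
                    "n_converted": n_conv,
                    "n_other": n_other,
                    "chemistry": chemistry,
                    "dedup_mode": dedup_mode,
                }
            )
    return pd.DataFrame(rows)


def methylation_level(pileup_df: pd.DataFrame, min_coverage: int = MIN_COVERAGE) -> pd.DataFrame:
    """Non-conversion level per site: n_unconverted / (n_unconverted + n_converted).

    Bases other than C/T are treated as sequencing error and excluded from
    the denominator.  Sites with coverage below ``min_coverage`` get a
    missing (NaN) level.  A binomial standard error accompanies each level.
    """
    df = pileup_df.copy()
    informative = df["n_unconverted"] + df["n_converted"]
    with np.errstate(invalid="ignore", divide="ignore"):
        level = df["n_unconverted"] / informative
        se = np.sqrt(level * (1.0 - level) / informative)
    low = df["coverage"] < min_coverage
    df["level"] = level.where(~low & (informative > 0))
    df["level_se"] = se.where(~low & (informative > 0))
    df["n_informative"] = informative
    return df


def call_sites(level_df: pd.DataFrame, min_level: float = 0.1) -> pd.DataFrame:
    """Sites whose non-conversion level exceeds ``min_level``.

    The cutoff separates genuine modification from bisulfite
    non-conversion background (gamma ~ 0.5%); 10% is comfortably above
    background at the coverages used here.
    """
    return level_df[level_df["level"] > min_level].reset_index(drop=True)


def read_matrix(
    alignments: list[BsAlignment], bundle: ReferenceBundle, gene_id: str
) -> pd.DataFrame:
    """Read-by-cytosine matrix for one gene (heatmap export).

    Rows are reads in input order, columns the gene's reference-C
    seq indices; entries are 'unconverted', 'converted', 'other' or
    'missing'.
    """
    g = bundle.gene(gene_id)
    cpos = _gene_c_positions(bundle, g)
    rows = []
    for aln in alignments:
        if aln.contig != g.contig or aln.strand != g.strand:
            continue
        if aln.left >= g.end or aln.left + len(aln.read) <= g.start:
            continue
        row = {}
        for idx, pos in cpos:
            base = _read_base_at(aln, pos)
            if base is None:
                row[idx] = "missing"
            elif base == "C":
                row[idx] = "unconverted"
            elif base == "T":
                row[idx] = "converted"
            else:
                row[idx] = "other"
        rows.append(row)
    return pd.DataFrame(rows, columns=[idx for idx, _ in cpos])


def _clamp01(x):
    return np.clip(x, 0.0, 1.0)


def deconvolve(
    levels_bs: pd.DataFrame,
    levels_redbs: pd.DataFrame | None = None,
    levels_fcab: pd.DataFrame | None = None,
    rho: float | None = None,
    pi: float | None = None,
) -> pd.DataFrame:
    """Three-chemistry m5C(+hm5C) vs f5C deconvolution per site.

    Joins the per-chemistry level tables on (gene_id, seq_index); missing
    levels propagate to missing estimates.  When ``rho``/``pi`` are given,
    efficiency-corrected f5C estimates (divided by the efficiency) are
    added; zero efficiencies are rejected.
    """
    if rho is not None and rho == 0:
        raise ValueError("rho must be nonzero for efficiency correction")
    if pi is not None and pi == 0:
        raise ValueError("pi must be nonzero for efficiency correction")

    def slim(df, name):
        return df[["gene_id", "seq_index", "level", "level_se"]].rename(
            columns={"level": f"level_{name}", "level_se": f"se_{name}"}
        )

    out = slim(levels_bs, "bs")
    for df, name in ((levels_redbs, "redbs"), (levels_fcab, "fcab")):
        if df is not None:
            out = out.merge(slim(df, name), on=["gene_id", "seq_index"], how="outer")
        else:
            out[f"level_{name}"] = np.nan
            out[f"se_{name}"] = np.nan
    out["est_m5c_hm5c"] = out["level_bs"]
    out["se_m5c_hm5c"] = out["se_bs"]
    for name, eff in (("redbs", rho), ("fcab", pi)):
        diff = out[f"level_{name}"] - out["level_bs"]
        est = _clamp01(diff)
        se = np.sqrt(out[f"se_{name}"] ** 2 + out["se_bs"] ** 2)
        suffix = "red" if name == "redbs" else "fcab"
        out[f"est_f5c_{suffix}"] = est
        out[f"se_f5c_{suffix}"] = se
        if eff is not None:
            out[f"est_f5c_{suffix}_corrected"] = _clamp01(est / eff)
    return out


def compare_conditions(result_a: pd.DataFrame, result_b: pd.DataFrame) -> pd.DataFrame:
    """Per-site deltas (a - b) of levels and estimates with pooled s.e.

    No hypothesis test is attached; the deltas and pooled binomial
    standard errors are descriptive.
    """
    merged = result_a.merge(
        result_b, on=["gene_id", "seq_index"], suffixes=("_a", "_b")
    )
    out = merged[["gene_id", "seq_index"]].copy()
    for col in ("level_bs", "level_redbs", "level_fcab", "est_m5c_hm5c",
                "est_f5c_red", "est_f5c_fcab"):
        if f"{col}_a" in merged:
            out[f"delta_{col}"] = merged[f"{col}_a"] - merged[f"{col}_b"]
    for se_col, col in (
        ("se_bs", "level_bs"),
        ("se_redbs", "level_redbs"),
        ("se_fcab", "level_fcab"),
        ("se_f5c_red", "est_f5c_red"),
        ("se_f5c_fcab", "est_f5c_fcab"),
    ):
        if f"{se_col}_a" in merged:
            out[f"se_delta_{col}"] = np.sqrt(
                merged[f"{se_col}_a"] ** 2 + merged[f"{se_col}_b"] ** 2
            )
    return out
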