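"""miCLIP methylation-site calling from raw FASTQ.

Pipeline stages, mirroring how truncation-based iCLIP data are processed:

1. barcode parsing — a 6-nt random UMI at read positions 1-3 and 8-10
   (1-based) traces individual cDNAs; positions 4-7 hold the sample
   barcode; the insert starts at position 11;
2. demultiplexing and UMI deduplication — reads with identical UMIs are
   PCR products; the number of distinct UMIs per unique insert is the
   cDNA count;
3. 3' adapter trimming (mismatch-only emulation of cutadapt -O 4 -e 0.06)
   and an 18-nt minimum-length filter;
4. unique alignment allowing one mismatch (best-stratum uniqueness);
5. truncation->cytosine assignment: the RT stall sits one base 5' of the
   read start in transcript sense, and counts go to the nearest
   transcript-sense C within +/-2 nt (ties broken 5');
6. RPM normalisation per replicate and the >50 RPM in >=2-of-3 replicate
   high-confidence filter.

Counters are kept at every stage so the conservation identities
(raw = parsed + short; cDNAs = unique + multimapper + unmapped;
aligned = assigned + unassigned) can be checked.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from . import _align
from .refmodel import Genome, ReferenceBundle
from .simulate import DEFAULT_ADAPTER

UMI_LEN = 6
BARCODE_LEN = 4
PREFIX_LEN = 10


@dataclass(frozen=True)
class ParsedRead:
    umi: str
    sample_barcode: str
    insert: str


@dataclass(frozen=True)
class CdnaRecord:
    insert: str
    cdna_count: int


@dataclass(frozen=True)
class TruncationAlignment:
    contig: str
    strand: str
    first_aligned_pos: int  # 0-based, 5'-most aligned base in transcript sense
    mismatches: int
    cdna_count: int


def parse_barcode(raw_read: str) -> ParsedRead | None:
    """Split a raw read into UMI, sample barcode and insert.

    Returns None for reads shorter than the 10-nt barcode prefix (the
    caller counts the discard).
    """
    if len(raw_read) < PREFIX_LEN:
        return None
    umi = raw_read[0:3] + raw_read[7:10]
    barcode = raw_read[3:7]
    return ParsedRead(umi, barcode, raw_read[10:])


def demultiplex_and_dedup(
    parsed_reads, expected_barcode: str, counters: Counter | None = None
) -> list[CdnaRecord]:
    """Keep exact barcode matches; collapse PCR duplicates via UMIs.

    For each unique insert the cDNA count is the number of distinct UMIs
    observed for it.  Output order follows first appearance of an insert.
    """
    if counters is None:
        counters = Counter()
    umis_by_insert: dict[str, set[str]] = {}
    for pr in parsed_reads:
        if pr.sample_barcode != expected_barcode:
            counters["barcode_mismatch"] += 1
            continue
        counters["barcode_matched"] += 1
        umis_by_insert.setdefault(pr.insert, set()).add(pr.umi)
    return [CdnaRecord(ins, len(u)) for ins, u in umis_by_insert.items()]


def trim_adapter(
    insert: str,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 4,
    max_error_rate: float = 0.06,
) -> str:
    """Remove a 3' adapter by mismatch-only suffix/prefix matching.

    The longest suffix of the insert that matches a prefix of the adapter
    with at least ``min_overlap`` bases and at most
    floor(max_error_rate * matched length) mismatches is removed; if no
    suffix qualifies the insert is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    for L in range(min(len(insert), len(adapter)), min_overlap - 1, -1):
        suffix = insert[-L:]
        budget = int(max_error_rate * L)
        mism = 0
        for a, b in zip(suffix, adapter):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        if mism <= budget:
            return insert[:-L]
    return insert


def length_filter(
    records: list[CdnaRecord], min_len: int = 18, counters: Counter | None = None
) -> list[CdnaRecord]:
    """Drop records whose insert is shorter than ``min_len``."""
    if counters is None:
        counters = Counter()
    kept = []
    for rec in records:
        if len(rec.insert) >= min_len:
            kept.append(rec)
        else:
            counters["too_short"] += 1
    return kept


def align_unique(
    record: CdnaRecord | str, genome: Genome, max_mismatch: int = 1
) -> TruncationAlignment | None:
    """Best-stratum unique alignment of an insert against both strands.

    Accepts iff the best non-empty mismatch stratum (exact first, then one
    mismatch) holds exactly one hit; multimappers and unmapped reads give
    None.
    """
    if isinstance(record, str):
        record = CdnaRecord(record, 1)
    hits = _align.scan_hits(record.insert, genome, max_mismatch)
    hit, category = _align.best_stratum_unique(hits)
    if hit is None:
        return None
    return TruncationAlignment(
        hit.contig, hit.strand, hit.first_aligned_pos, hit.mismatches, record.cdna_count
    )


def assign_truncation(alignment: TruncationAlignment, genome: Genome) -> int | None:
    """0-based genomic position of the cytosine a truncation is assigned to.

    The stall sits one base 5' (transcript sense) of the first aligned
    base.  The candidate is the transcript-sense cytosine nearest to the
    stall within +/-2 nt, ties broken toward the 5' side; None if the
    window holds no C or the stall falls off the contig.
    """
    n = genome.length(alignment.contig)
    if alignment.strand == "+":
        stall = alignment.first_aligned_pos - 1
        five_prime = -1  # smaller genomic coordinate
        c_base = "C"
    else:
        stall = alignment.first_aligned_pos + 1
        five_prime = +1
        c_base = "G"  # transcript-sense C of a '-' gene is forward-strand G
    if not (0 <= stall < n):
        return None
    for dist in (0, 1, 2):
        for sign in (five_prime, -five_prime):
            pos = stall + sign * dist
            if 0 <= pos < n and genome.base(alignment.contig, pos) == c_base:
                return pos
            if dist == 0:
                break
    return None


# ---------------------------------------------------------------------------
# replicate pipeline


@dataclass
class ReplicateResult:
    """Per-replicate assignment table, library total and stage counters."""

    assignments: pd.DataFrame  # contig, strand, pos (0-based), cdna_count
    total_unique_cdna: int  # RPM denominator: uniquely mapped cDNA counts
    counters: Counter


def process_replicate(
    fastq_path,
    genome: Genome,
    expected_barcode: str,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 4,
    max_error_rate: float = 0.06,
    min_len: int = 18,
    max_mismatch: int = 1,
) -> ReplicateResult:
    """Run one miCLIP replicate FASTQ through all calling stages."""
    counters: Counter = Counter()
    parsed: list[ParsedRead] = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        counters["raw_reads"] += 1
        pr = parse_barcode(str(rec.seq))
        if pr is None:
            counters["too_short_raw"] += 1
        else:
            parsed.append(pr)
    counters["parsed"] = len(parsed)

    records = demultiplex_and_dedup(parsed, expected_barcode, counters)
    counters["cdna_records"] = len(records)

    records = [
        CdnaRecord(trim_adapter(r.insert, adapter, min_overlap, max_error_rate), r.cdna_count)
        for r in records
    ]
    records = length_filter(records, min_len, counters)
    counters["after_length_filter"] = len(records)

    # distinct inserts dominate runtime; memoise the scan
    cache: dict[str, tuple[TruncationAlignment | None, str]] = {}
    rows = []
    total_unique_cdna = 0
    for rec in records:
        if rec.insert in cache:
            base, category = cache[rec.insert]
        else:
            hits = _align.scan_hits(rec.insert, genome, max_mismatch)
            hit, category = _align.best_stratum_unique(hits)
            base = (
                None
                if hit is None
                else TruncationAlignment(
                    hit.contig, hit.strand, hit.first_aligned_pos, hit.mismatches, 1
                )
            )
            cache[rec.insert] = (base, category)
        if base is None:
            counters[category] += 1
            continue
        counters["unique"] += 1
        aln = TruncationAlignment(
            base.contig, base.strand, base.first_aligned_pos, base.mismatches, rec.cdna_count
        )
        total_unique_cdna += rec.cdna_count
        pos = assign_truncation(aln, genome)
        if pos is None:
            counters["unassigned"] += 1
            continue
        counters["assigned"] += 1
        rows.append(
            {
                "contig": aln.contig,
                "strand": aln.strand,
                "pos": pos,
                "cdna_count": rec.cdna_count,
            }
        )
    assignments = pd.DataFrame(rows, columns=["contig", "strand", "pos", "cdna_count"])
    if not assignments.empty:
        assignments = (
            assignments.groupby(["contig", "strand", "pos"], as_index=False)["cdna_count"]
            .sum()
            .sort_values(["contig", "pos"], kind="stable")
            .reset_index(drop=True)
        )
    return ReplicateResult(assignments, total_unique_cdna, counters)


def build_site_table(
    replicates: list[ReplicateResult],
    bundle: ReferenceBundle | None = None,
    threshold_rpm: float = 50.0,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Merge replicate assignments into the per-cytosine site table.

    RPM is computed per replicate against that replicate's uniquely mapped
    cDNA total; a site is high confidence iff its RPM strictly exceeds
    ``threshold_rpm`` in at least ``min_replicates`` replicates.  Reported
    positions are 1-based.
    """
    n_rep = len(replicates)
    if min_replicates > n_rep:
        raise ValueError("min_replicates exceeds the number of replicates")
    keys: dict[tuple, dict] = {}
    for i, rep in enumerate(replicates):
        denom = rep.total_unique_cdna
        for row in rep.assignments.itertuples(index=False):
            key = (row.contig, row.strand, row.pos)
            entry = keys.setdefault(key, {})
            entry[f"cdna_count_rep{i + 1}"] = int(row.cdna_count)
            entry[f"rpm_rep{i + 1}"] = (
                row.cdna_count / denom * 1e6 if denom > 0 else 0.0
            )
    rows = []
    for (contig, strand, pos), entry in sorted(keys.items()):
        row = {"contig": contig, "position": pos + 1, "strand": strand}
        gene_id = None
        if bundle is not None:
            genes = bundle.genes_overlapping(contig, pos, strand)
            if genes:
                gene_id = genes[0].gene_id
        row["gene_id"] = gene_id
        n_passing = 0
        for i in range(1, n_rep + 1):
            count = entry.get(f"cdna_count_rep{i}", 0)
            rpm = entry.get(f"rpm_rep{i}", 0.0)
            row[f"cdna_count_rep{i}"] = count
            row[f"rpm_rep{i}"] = rpm
            if rpm > threshold_rpm:
                n_passing += 1
        row["n_replicates_passing"] = n_passing
        row["high_confidence"] = n_passing >= min_replicates
        rows.append(row)
    cols = ["contig", "position", "strand", "gene_id"]
    for i in range(1, n_rep + 1):
        cols += [f"cdna_count_rep{i}", f"rpm_rep{i}"]
    cols += ["n_replicates_passing", "high_confidence"]
    return pd.DataFrame(rows, columns=cols)


def composition_report(site_table: pd.DataFrame, bundle: ReferenceBundle) -> pd.DataFrame:
    """Per-gene shares of pooled cDNA counts, overall and among tRNA loci.

    Pools the per-replicate cDNA counts of every site, groups them by
    overlapping gene (unannotated positions form their own category) and
    reports each gene's share of all counts and, for tRNA-biotype genes,
    of the tRNA-locus total.  Shares each sum to 1 over their categories.
    """
    count_cols = [c for c in site_table.columns if c.startswith("cdna_count_rep")]
    biotype = {a.gene_id: a.biotype for a in bundle.annotations}
    totals: dict[str, int] = {}
    for row in site_table.itertuples(index=False):
        gene = row.gene_id if row.gene_id is not None else "(unannotated)"
        pooled = sum(int(getattr(row, c)) for c in count_cols)
        totals[gene] = totals.get(gene, 0) + pooled
    grand = sum(totals.values())
    trna_total = sum(
        n for g, n in totals.items() if biotype.get(g) == "tRNA"
    )
    rows = []
    for gene in sorted(totals, key=lambda g: -totals[g]):
        bt = biotype.get(gene, "other" if gene != "(unannotated)" else None)
        rows.append(
            {
                "gene_id": gene,
                "biotype": bt,
                "cdna_count": totals[gene],
                "share_all": totals[gene] / grand if grand else float("nan"),
                "share_trna": (
                    totals[gene] / trna_total
                    if bt == "tRNA" and trna_total
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
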