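"""Ground-truthed read simulation for miCLIP, bisulfite-family and CLIP libraries.

The generator emulates the statistical structure the downstream callers
assume:

* tRNA molecule populations with per-position cytosine modification states
  (unmodified C, m5C, hm5C, f5C);
* chemistry-specific C->T conversion: plain bisulfite deaminates C and f5C
  but protects m5C/hm5C; NaBH4 reduction (RedBS) and O-ethylhydroxylamine
  protection (fCAB) additionally shield f5C with efficiencies rho and pi;
* miCLIP cDNAs that truncate one base 3' of the crosslinked cytosine with
  +/-2 nt jitter, carry a 6-nt split UMI plus 4-nt sample barcode in the
  first ten read bases, read through into the sequencing adapter, and are
  PCR-duplicated;
* CLIP footprint libraries with per-gene negative-binomial read counts and
  30-60 nt fragments.

Every library writer is deterministic under its seed and writes a TSV truth
sidecar so recovery can be checked against the simulated ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refmodel import ReferenceBundle, revcomp

#: modification states and their single-character molecule codes
STATES = ("C", "M5C", "HM5C", "F5C")
STATE_CODE = {"C": "C", "M5C": "m", "HM5C": "h", "F5C": "f"}
CODE_STATE = {v: k for k, v in STATE_CODE.items()}

DEFAULT_ADAPTER = "AGATCGGAAGAGCGGTTCAG"

#: defaults for the chemistry efficiencies the study leaves unquantified:
#: gamma = bisulfite non-conversion of unmodified C, rho = NaBH4 reduction
#: efficiency of f5C, pi = O-ethylhydroxylamine protection efficiency.
DEFAULT_GAMMA = 0.005
DEFAULT_RHO = 0.9
DEFAULT_PI = 0.9

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SiteSpec:
    """Modification-state composition at one cytosine of one gene."""

    gene_id: str
    seq_index: int
    state_probs: dict[str, float]

    def __post_init__(self):
        probs = dict(self.state_probs)
        unknown = set(probs) - set(STATES)
        if unknown:
            raise SimulationError(f"unknown states {sorted(unknown)}")
        if any(p < 0 for p in probs.values()):
            raise SimulationError("negative state probability")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise SimulationError("state probabilities must sum to 1")
        object.__setattr__(self, "state_probs", probs)

    def prob(self, state: str) -> float:
        return self.state_probs.get(state, 0.0)


@dataclass(frozen=True)
class ChemistrySpec:
    """Per-state probability that a position reads as T after treatment.

    ``gamma`` is the failed-conversion probability for unmodified C: an
    unmodified C reads as C with probability gamma even under complete
    treatment.
    """

    name: str
    conversion_prob: dict[str, float]
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self):
        for state, p in self.conversion_prob.items():
            if state not in STATES:
                raise SimulationError(f"unknown state {state!r}")
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"conversion prob for {state} not in [0,1]")
        if not (0.0 <= self.gamma <= 1.0):
            raise SimulationError("gamma not in [0,1]")

    def p_reads_t(self, state: str) -> float:
        """Effective probability that ``state`` is read as T."""
        p = self.conversion_prob[state]
        if state == "C":
            p *= 1.0 - self.gamma
        return p


def bs_spec(gamma: float = DEFAULT_GAMMA) -> ChemistrySpec:
    """Plain bisulfite: C and f5C deaminate, m5C/hm5C are protected."""
    return ChemistrySpec("BS", {"C": 1.0, "M5C": 0.0, "HM5C": 0.0, "F5C": 1.0}, gamma)


def redbs_spec(gamma: float = DEFAULT_GAMMA, rho: float = DEFAULT_RHO) -> ChemistrySpec:
    """NaBH4 reduction then bisulfite: f5C protected with efficiency rho."""
    return ChemistrySpec(
        "RedBS", {"C": 1.0, "M5C": 0.0, "HM5C": 0.0, "F5C": 1.0 - rho}, gamma
    )


def fcab_spec(gamma: float = DEFAULT_GAMMA, pi: float = DEFAULT_PI) -> ChemistrySpec:
    """O-ethylhydroxylamine then bisulfite: f5C protected with efficiency pi."""
    return ChemistrySpec(
        "fCAB", {"C": 1.0, "M5C": 0.0, "HM5C": 0.0, "F5C": 1.0 - pi}, gamma
    )


def chemistry_by_name(name: str, gamma=DEFAULT_GAMMA, rho=DEFAULT_RHO, pi=DEFAULT_PI):
    table = {
        "BS": lambda: bs_spec(gamma),
        "RedBS": lambda: redbs_spec(gamma, rho),
        "fCAB": lambda: fcab_spec(gamma, pi),
    }
    try:
        return table[name]()
    except KeyError:
        raise SimulationError(f"unknown chemistry {name!r}") from None


@dataclass(frozen=True)
class MiclipSpec:
    """Layout and noise model of a simulated miCLIP library.

    ``crosslink_weights`` maps (gene_id, seq_index) to relative crosslink
    intensity; ``truncation_offset_probs`` is the distribution of the RT
    stall offset delta relative to the crosslinked cytosine (the raw
    insert starts at site + delta + 1 in transcript sense).  The raw read
    is UMI(3) + sample barcode(4) + UMI(3) + insert + adapter read-through.
    Insert 3' ends are drawn uniformly between ``min_insert`` and
    ``max_insert``, emulating partial RNase I digestion of the captured
    RNA; inserts may read past the mature tRNA 3' end into downstream
    precursor sequence, since mitochondrial transcription is polycistronic
    and the assay captures precursor RNA.
    """

    crosslink_weights: dict[tuple[str, int], float]
    truncation_offset_probs: dict[int, float] = field(
        default_factory=lambda: {-2: 0.05, -1: 0.20, 0: 0.50, 1: 0.20, 2: 0.05}
    )
    sample_barcode: str = "ACGT"
    adapter: str = DEFAULT_ADAPTER
    pcr_duplication: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    seq_error_rate: float = 0.001
    min_insert: int = 20
    max_insert: int = 50

    def __post_init__(self):
        if not self.crosslink_weights:
            raise SimulationError("crosslink_weights is empty")
        if any(w < 0 for w in self.crosslink_weights.values()):
            raise SimulationError("negative crosslink weight")
        if abs(sum(self.truncation_offset_probs.values()) - 1.0) > 1e-9:
            raise SimulationError("offset probabilities must sum to 1")
        if any(abs(d) > 2 for d in self.truncation_offset_probs):
            raise SimulationError("truncation offsets must lie in [-2, 2]")
        if len(self.sample_barcode) != 4:
            raise SimulationError("sample barcode must be 4 nt")
        if any(k < 1 for k in self.pcr_duplication):
            raise SimulationError("duplicate counts must be >= 1")
        if abs(sum(self.pcr_duplication.values()) - 1.0) > 1e-9:
            raise SimulationError("duplication probabilities must sum to 1")


@dataclass
class MoleculePopulation:
    """Simulated molecules of one gene plus their realised ground truth.

    Each molecule is a string over {A,C,G,T,m,h,f} in transcript sense;
    ``truth`` maps seq_index -> realised state fractions at each simulated
    site.
    """

    gene_id: str
    molecules: list[str]
    truth: dict[int, dict[str, float]]

    @property
    def n(self) -> int:
        return len(self.molecules)


# ---------------------------------------------------------------------------
# molecule sampling


def sample_molecules(
    bundle: ReferenceBundle,
    site_specs: list[SiteSpec],
    n_per_gene: int,
    seed: int,
    genes: list[str] | None = None,
) -> dict[str, MoleculePopulation]:
    """Draw ``n_per_gene`` molecules per gene with per-site state sampling.

    Positions without a :class:`SiteSpec` keep their reference base (Cs stay
    unmodified C).  Raises if a site's reference base is not C on the
    transcript strand.
    """
    if n_per_gene < 1:
        raise SimulationError("n_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = sorted({s.gene_id for s in site_specs})
    specs_by_gene: dict[str, list[SiteSpec]] = {g: [] for g in genes}
    for s in site_specs:
        if s.gene_id not in specs_by_gene:
            raise SimulationError(
                f"site spec for {s.gene_id!r} but gene not in simulated set"
            )
        specs_by_gene[s.gene_id].append(s)

    out: dict[str, MoleculePopulation] = {}
    for gene_id in genes:
        seq = bundle.transcript_sequence(gene_id)
        columns: dict[int, np.ndarray] = {}
        truth: dict[int, dict[str, float]] = {}
        for spec in specs_by_gene[gene_id]:
            if not (0 <= spec.seq_index < len(seq)):
                raise SimulationError(
                    f"site index {spec.seq_index} outside gene {gene_id!r}"
                )
            if seq[spec.seq_index] != "C":
                raise SimulationError(
                    f"site {gene_id}:{spec.seq_index} reference base is "
                    f"{seq[spec.seq_index]!r}, not C"
                )
            states = [st for st in STATES if spec.prob(st) > 0]
            probs = np.array([spec.prob(st) for st in states])
            drawn = rng.choice(len(states), size=n_per_gene, p=probs)
            codes = np.array([STATE_CODE[st] for st in states])[drawn]
            columns[spec.seq_index] = codes
            truth[spec.seq_index] = {
                st: float(np.mean(codes == STATE_CODE[st])) for st in STATES
            }
        template = list(seq)
        molecules = []
        for i in range(n_per_gene):
            mol = template.copy()
            for idx, codes in columns.items():
                mol[idx] = codes[i]
            molecules.append("".join(mol))
        out[gene_id] = MoleculePopulation(gene_id, molecules, truth)
    return out


# ---------------------------------------------------------------------------
# chemistry


def apply_chemistry(molecule: str, chem: ChemistrySpec, rng: np.random.Generator) -> str:
    """Convert one molecule: per-position independent Bernoulli conversion.

    Cytosine states read as T with the chemistry's effective probability;
    non-C bases pass through unchanged.
    """
    u = rng.random(len(molecule))
    out = []
    for ch, x in zip(molecule, u):
        state = CODE_STATE.get(ch)
        if state is None:
            out.append(ch)
        else:
            out.append("T" if x < chem.p_reads_t(state) else "C")
    return "".join(out)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _write_fastq(path, reads: list[tuple[str, str]]):
    """Write (name, sequence) pairs as Phred+33 FASTQ with constant Q40."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# library writers


def make_bs_library(
    populations: dict[str, MoleculePopulation],
    chem: ChemistrySpec,
    coverage: int,
    seq_error_rate: float,
    seed: int,
    out_fastq,
    truth_out=None,
) -> pd.DataFrame:
    """Write a directional bisulfite-family library of full-length reads.

    For each gene, ``coverage`` molecules are drawn with replacement from
    the population, converted under ``chem``, and written transcript-sense
    at constant quality.  Returns (and optionally writes) the truth table
    of per-site state fractions and parameters.
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for gene_id in sorted(populations):
        pop = populations[gene_id]
        picks = rng.integers(0, pop.n, size=coverage)
        for j, i in enumerate(picks):
            conv = apply_chemistry(pop.molecules[i], chem, rng)
            conv = _add_errors(conv, seq_error_rate, rng)
            reads.append((f"{chem.name.lower()}:{gene_id}:{j}", conv))
        for idx, fracs in sorted(pop.truth.items()):
            row = {
                "gene_id": gene_id,
                "seq_index": idx,
                "chemistry": chem.name,
                "coverage": coverage,
                "gamma": chem.gamma,
                "seq_error_rate": seq_error_rate,
                "seed": seed,
            }
            row.update({f"frac_{st}": fracs[st] for st in STATES})
            truth_rows.append(row)
    _write_fastq(out_fastq, reads)
    truth = pd.DataFrame(truth_rows)
    if truth_out is not None:
        truth.to_csv(truth_out, sep="\t", index=False)
    return truth


def make_miclip_library(
    bundle: ReferenceBundle,
    spec: MiclipSpec,
    n_cdna: int,
    seed: int,
    out_fastq,
    truth_out=None,
) -> pd.DataFrame:
    """Write a raw miCLIP FASTQ of ``n_cdna`` cDNAs plus PCR duplicates.

    Geometry: the RT stall leaves the cDNA starting one base 3' of the
    crosslinked cytosine, jittered by delta drawn from
    ``truncation_offset_probs``; the insert runs from there to a uniformly
    drawn 3' end.  Duplicates of one cDNA are byte-identical (sequencing
    errors are applied once per cDNA, on the insert only).  The truth
    sidecar gives per-site cDNA counts, distinct (insert, UMI) pairs and
    raw read counts.
    """
    if n_cdna < 1:
        raise SimulationError("n_cdna must be >= 1")
    rng = np.random.default_rng(seed)
    sites = sorted(spec.crosslink_weights)
    for gene_id, idx in sites:
        seq = bundle.transcript_sequence(gene_id)
        if not (0 <= idx < len(seq)) or seq[idx] != "C":
            raise SimulationError(
                f"crosslink weight on {gene_id}:{idx}, which is not a "
                "transcript-strand C"
            )

    def precursor_tail(gene_id: str, start_idx: int) -> str:
        """Transcript-sense sequence from within-gene index ``start_idx``,
        reading up to max_insert nt past the mature 3' end into downstream
        precursor sequence (mitochondrial transcription is polycistronic,
        and the captured RNA includes precursors)."""
        ann = bundle.gene(gene_id)
        contig = bundle.genome[ann.contig]
        if ann.strand == "+":
            g0 = ann.start + start_idx
            return contig[g0 : min(g0 + spec.max_insert, len(contig))]
        g1 = ann.end - start_idx
        g0 = max(g1 - spec.max_insert, 0)
        return revcomp(contig[g0:g1])
    weights = np.array([spec.crosslink_weights[s] for s in sites], dtype=float)
    weights /= weights.sum()
    offsets = sorted(spec.truncation_offset_probs)
    offset_p = np.array([spec.truncation_offset_probs[d] for d in offsets])
    dups = sorted(spec.pcr_duplication)
    dup_p = np.array([spec.pcr_duplication[k] for k in dups])

    site_idx = rng.choice(len(sites), size=n_cdna, p=weights)
    delta_idx = rng.choice(len(offsets), size=n_cdna, p=offset_p)
    dup_counts = np.array(dups)[rng.choice(len(dups), size=n_cdna, p=dup_p)]
    umis = _BASES[rng.integers(0, 4, size=(n_cdna, 6))]

    reads: list[tuple[str, str]] = []
    per_site_cdna: dict[tuple[str, int], int] = {s: 0 for s in sites}
    per_site_raw: dict[tuple[str, int], int] = {s: 0 for s in sites}
    pairs_by_site: dict[tuple[str, int], set] = {s: set() for s in sites}
    for i in range(n_cdna):
        gene_id, c_idx = sites[site_idx[i]]
        start = c_idx + offsets[delta_idx[i]] + 1
        if start < 0:
            continue  # stall jittered off the transcript 5' end; cDNA lost
        tail = precursor_tail(gene_id, start)
        if not tail:
            continue
        hi = min(len(tail), spec.max_insert)
        lo = min(spec.min_insert, hi)
        length = int(rng.integers(lo, hi + 1))
        insert = _add_errors(tail[:length], spec.seq_error_rate, rng)
        umi = umis[i].tobytes().decode("ascii")
        raw = umi[:3] + spec.sample_barcode + umi[3:] + insert + spec.adapter
        k = int(dup_counts[i])
        for j in range(k):
            reads.append((f"cdna{i}.{j}", raw))
        site = (gene_id, c_idx)
        per_site_cdna[site] += 1
        per_site_raw[site] += k
        pairs_by_site[site].add((insert, umi))
    _write_fastq(out_fastq, reads)
    truth_rows = [
        {
            "gene_id": g,
            "seq_index": idx,
            "n_cdna": per_site_cdna[(g, idx)],
            "n_distinct_insert_umi": len(pairs_by_site[(g, idx)]),
            "n_raw_reads": per_site_raw[(g, idx)],
            "weight": spec.crosslink_weights[(g, idx)],
            "seed": seed,
        }
        for g, idx in sites
    ]
    truth = pd.DataFrame(truth_rows)
    if truth_out is not None:
        truth.to_csv(truth_out, sep="\t", index=False)
    return truth


def make_hitsclip_library(
    bundle: ReferenceBundle,
    per_gene_means: dict[str, float],
    dispersion: float,
    seed: int,
    out_fastq,
    truth_out=None,
    fragment_range: tuple[int, int] = (30, 60),
) -> pd.DataFrame:
    """Write a CLIP footprint library with negative-binomial gene counts.

    Per-gene read counts are NB(mean, dispersion) (variance mu + phi*mu^2);
    each read is a transcript-sense fragment with uniform start and length
    uniform in ``fragment_range``, clipped to the gene.
    """
    if dispersion <= 0:
        raise SimulationError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = fragment_range
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for gene_id in sorted(per_gene_means):
        mu = per_gene_means[gene_id]
        seq = bundle.transcript_sequence(gene_id)
        r = 1.0 / dispersion
        count = int(rng.negative_binomial(r, r / (r + mu))) if mu > 0 else 0
        for j in range(count):
            length = int(rng.integers(lo, hi + 1))
            length = min(length, len(seq))
            start = int(rng.integers(0, len(seq) - length + 1))
            reads.append((f"clip:{gene_id}:{j}", seq[start : start + length]))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "mean": mu,
                "count": count,
                "dispersion": dispersion,
                "seed": seed,
            }
        )
    _write_fastq(out_fastq, reads)
    truth = pd.DataFrame(truth_rows)
    if truth_out is not None:
        truth.to_csv(truth_out, sep="\t", index=False)
    return truth
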