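"""Bundled synthetic references and study-condition defaults.

`toy_mito_bundle` builds a deterministic ~3 kb synthetic mitochondrial
mini-genome carrying the loci the analysis revolves around (MT-TM and the
other m5C-bearing mt-tRNAs, MT-ND1, an rRNA and an mRNA filler locus).
Sequences are random but fixed; the designated crosslink cytosines of the
single-site loci sit in locally C-free context (no other C within +/-4 nt)
so truncation assignment is unambiguous, matching the observation that
miCLIP reads truncate predominantly at single cytosines.

`fig_composition_weights` encodes the reported mitochondrial miCLIP read
composition (MT-TM 26% of mtDNA-mapped reads and 60% of mt-tRNA loci,
MT-ND1 15%, MT-TL1 5%, MT-TS2 4.5%); the residual tRNA and non-tRNA mass
is split over the remaining loci.  `m5c_catalogue` lists the eight
catalogued cytosine-5 methylations in six mt-tRNAs (C34 of mt-tRNA(Met),
C48 of mt-tRNA(Leu,UUR), C48-50 of mt-tRNA(Ser,AGY), C49 of mt-tRNA(Glu),
C47 of mt-tRNA(His) and C47 of mt-tRNA(Phe)) as sequential toy-gene
indices.
"""

from __future__ import annotations

import numpy as np

from .refmodel import Genome, GeneAnnotation, ReferenceBundle, TrnaLayout

_TOY_SEED = 20160630
_SPACER = 25

# gene_id, biotype, length, anticodon_start (tRNAs), designated miCLIP site
_TOY_GENES = [
    ("MT-TF", "tRNA", 70, 32, 46),
    ("MT-RNR1", "rRNA", 500, None, 250),
    ("MT-TM", "tRNA", 68, 30, 30),
    ("MT-ND1", "mRNA", 600, None, 300),
    ("MT-TL1", "tRNA", 70, 31, 47),
    ("MT-TS2", "tRNA", 68, 31, 48),
    ("MT-TE", "tRNA", 69, 32, 48),
    ("MT-TH", "tRNA", 68, 32, 46),
    ("MT-CO1", "mRNA", 700, None, 350),
]

#: the eight catalogued m5C sites in six mt-tRNAs, as sequential toy indices
_CATALOGUE = {
    "MT-TM": [30],
    "MT-TL1": [47],
    "MT-TS2": [47, 48, 49],
    "MT-TE": [48],
    "MT-TH": [46],
    "MT-TF": [46],
}

#: loci whose designated site is kept free of other Cs within +/-4 nt
_CLEAN_CONTEXT = {
    "MT-TF", "MT-RNR1", "MT-TM", "MT-ND1", "MT-TL1", "MT-TE", "MT-TH", "MT-CO1",
}


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def toy_mito_bundle() -> ReferenceBundle:
    """Deterministic synthetic mitochondrial mini-genome (contig ``MT``)."""
    rng = np.random.default_rng(_TOY_SEED)
    seq: list[str] = _random_seq(rng, _SPACER)
    annotations: list[GeneAnnotation] = []
    layouts: list[TrnaLayout] = []
    non_c = "AGT"
    for gene_id, biotype, length, ac_start, site in _TOY_GENES:
        gene_seq = _random_seq(rng, length)
        catalogue = _CATALOGUE.get(gene_id, [])
        for idx in catalogue:
            gene_seq[idx] = "C"
        gene_seq[site] = "C"
        if gene_id == "MT-TM":
            gene_seq[30], gene_seq[31], gene_seq[32] = "C", "A", "T"
        if gene_id in _CLEAN_CONTEXT:
            protected = set(catalogue) | {site}
            for off in range(-4, 5):
                p = site + off
                if 0 <= p < length and p not in protected and gene_seq[p] == "C":
                    gene_seq[p] = non_c[int(rng.integers(0, 3))]
        start = len(seq)
        seq.extend(gene_seq)
        annotations.append(
            GeneAnnotation(gene_id, "MT", start, start + length, "+", biotype)
        )
        if ac_start is not None:
            layouts.append(TrnaLayout(gene_id, ac_start, length))
        seq.extend(_random_seq(rng, _SPACER))
    genome = Genome({"MT": "".join(seq)})
    return ReferenceBundle(genome, annotations, layouts)


def m5c_catalogue() -> dict[str, list[int]]:
    """Catalogued mt-tRNA m5C sites as {gene_id: [seq_index, ...]}."""
    return {g: list(v) for g, v in _CATALOGUE.items()}


def miclip_site(gene_id: str) -> int:
    """The designated crosslink cytosine (seq index) of a toy locus."""
    for gid, _bt, _len, _ac, site in _TOY_GENES:
        if gid == gene_id:
            return site
    raise KeyError(gene_id)


def fig_composition_weights() -> dict[tuple[str, int], float]:
    """Crosslink weights reproducing the reported mitochondrial composition.

    MT-TM carries 26% of mtDNA-mapped reads (60% of the mt-tRNA loci),
    MT-ND1 15%, MT-TL1 5% and MT-TS2 4.5%; the remaining tRNA mass
    (26/0.60 - 35.5 = 7.83%) is split equally over MT-TE/MT-TH/MT-TF and
    the non-tRNA remainder over MT-RNR1 and MT-CO1.
    """
    trna_total = 0.26 / 0.60
    resid_trna = (trna_total - 0.26 - 0.05 - 0.045) / 3.0
    resid_other = 1.0 - trna_total - 0.15
    weights = {
        "MT-TM": 0.26,
        "MT-ND1": 0.15,
        "MT-TL1": 0.05,
        "MT-TS2": 0.045,
        "MT-TE": resid_trna,
        "MT-TH": resid_trna,
        "MT-TF": resid_trna,
        "MT-RNR1": resid_other * 0.6,
        "MT-CO1": resid_other * 0.4,
    }
    return {(g, miclip_site(g)): w for g, w in weights.items()}


def expected_composition() -> dict[str, float]:
    """Ground-truth shares implied by :func:`fig_composition_weights`."""
    w = fig_composition_weights()
    by_gene = {g: x for (g, _i), x in w.items()}
    trna = {"MT-TM", "MT-TL1", "MT-TS2", "MT-TE", "MT-TH", "MT-TF"}
    trna_total = sum(x for g, x in by_gene.items() if g in trna)
    return {
        "MT-TM_share_all": by_gene["MT-TM"],
        "MT-TM_share_trna": by_gene["MT-TM"] / trna_total,
        "MT-ND1_share_all": by_gene["MT-ND1"],
    }


def synthetic_rcrs_mt_tm() -> ReferenceBundle:
    """Synthetic stand-in for the rCRS MT-TM record (coordinate checks only).

    The gene boundaries are the real rCRS ones — MT-TM spans mtDNA
    4402-4469 (1-based) on the forward strand, with the wobble cytosine at
    sequential index 30, i.e. mtDNA position 4432 — but the sequence is a
    synthetic placeholder (random bases with a CAT anticodon at indices
    30-32), not NC_012920.  Coordinate arithmetic never reads the bases;
    supply the real record for sequence-level work.
    """
    rng = np.random.default_rng(_TOY_SEED + 1)
    n = 4469
    seq = _random_seq(rng, n)
    start = 4401  # 0-based
    seq[start + 30], seq[start + 31], seq[start + 32] = "C", "A", "T"
    genome = Genome({"chrM": "".join(seq)})
    ann = [GeneAnnotation("MT-TM", "chrM", start, start + 68, "+", "tRNA")]
    layouts = [TrnaLayout("MT-TM", 30, 68)]
    return ReferenceBundle(genome, ann, layouts)


def write_reference(bundle: ReferenceBundle, fasta_path, bed_path, layout_path):
    """Export a bundle to FASTA + BED6(+biotype) + layout TSV."""
    with open(fasta_path, "w") as fh:
        for name, seq in bundle.genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(bed_path, "w") as fh:
        for a in bundle.annotations:
            fh.write(
                f"{a.contig}\t{a.start}\t{a.end}\t{a.gene_id}\t0\t{a.strand}\t{a.biotype}\n"
            )
    with open(layout_path, "w") as fh:
        fh.write("gene_id\tanticodon_start\tlength\n")
        for lay in bundle.layouts:
            fh.write(f"{lay.gene_id}\t{lay.anticodon_start}\t{lay.length}\n")
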