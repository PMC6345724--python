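"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec (including the seed), so
fixtures are reproduced rather than stored: random DNA, gcPBM-style probe
tables whose ln-intensity is linear in the encoded features plus Gaussian
noise, SNP cohorts with a controlled mutation-type mix (default: the four
transitions at a combined 70%) and an optional planted excess of
high-|ddGs| variants inside TF binding sites, and a reference FASTA + VCF
pair with a truth table of trinucleotide contexts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import DNA_BASES
from .energy import DinucleotideTable, DifferenceMatrix
from .model import ProbeSet, encode_features
from .snp import DEFAULT_BINS, MUTATION_TYPES, SnpRecord, abs_bin

__all__ = [
    "GcpbmSpec",
    "SnpCohortSpec",
    "DEFAULT_TYPE_WEIGHTS",
    "gen_random_dna",
    "gen_gcpbm",
    "gen_snp_cohort",
    "gen_reference_with_snps",
]

_BASES = np.array(list(DNA_BASES))

#: Transitions (A>G, G>A, C>T, T>C) carry 70% of the probability mass,
#: matching the preference seen in phenotype-associated SNP cohorts; the
#: eight transversions share the remaining 30% uniformly.
DEFAULT_TYPE_WEIGHTS = {
    t: (0.175 if t in ("A>G", "G>A", "C>T", "T>C") else 0.30 / 8)
    for t in MUTATION_TYPES
}


def gen_random_dna(
    n: int, length: int, gc_fraction: float = 0.5, seed: int = 0
) -> list[str]:
    """i.i.d. random sequences with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    draws = rng.choice(_BASES, size=(n, length), p=p)
    return ["".join(row) for row in draws]


@dataclass
class GcpbmSpec:
    """Ground truth for a synthetic gcPBM probe set.

    ln-intensity = intercept + w . encoded(1mer+dgs features) + N(0, sd).
    Default weights mimic a TF motif: an 8-bp core of strong per-base
    weights plus moderate weights on every stacking column; pass explicit
    arrays to override. All draws come from ``seed``.
    """

    n_probes: int = 2000
    probe_length: int = 36
    core_width: int = 8
    onemer_weight_sd: float = 0.4
    stacking_weight_sd: float = 0.15
    intercept: float = 7.0
    noise_sd: float = 0.1
    gc_fraction: float = 0.5
    seed: int = 0
    onemer_weights: np.ndarray | None = field(default=None, repr=False)
    stacking_weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.probe_length < 3:
            raise ValueError("probe_length must be >= 3")


def _spec_weights(spec: GcpbmSpec, rng: np.random.Generator):
    k = spec.probe_length
    if spec.onemer_weights is not None:
        w1 = np.asarray(spec.onemer_weights, dtype=float)
        if w1.shape != (4 * k,):
            raise ValueError("onemer_weights must have shape (4K,)")
    else:
        w1 = np.zeros(4 * k)
        start = (k - spec.core_width) // 2
        for pos in range(start, start + spec.core_width):
            w1[4 * pos : 4 * pos + 4] = rng.normal(0, spec.onemer_weight_sd, 4)
    if spec.stacking_weights is not None:
        ws = np.asarray(spec.stacking_weights, dtype=float)
        if ws.shape != (k - 2,):
            raise ValueError("stacking_weights must have shape (K-2,)")
    else:
        ws = rng.normal(0, spec.stacking_weight_sd, k - 2)
    return w1, ws


def gen_gcpbm(
    spec: GcpbmSpec, table: DinucleotideTable
) -> tuple[ProbeSet, dict]:
    """Generate probes and return (ProbeSet, ground-truth record)."""
    rng = np.random.default_rng(spec.seed)
    w1, ws = _spec_weights(spec, rng)
    seqs = gen_random_dna(
        spec.n_probes,
        spec.probe_length,
        spec.gc_fraction,
        seed=int(rng.integers(2**31)),
    )
    dummy = ProbeSet(tuple(seqs), np.ones(spec.n_probes))
    fm = encode_features(dummy, table, "1mer+dgs")
    w = np.concatenate([w1, ws])
    ln_i = spec.intercept + fm.X @ w + rng.normal(0, spec.noise_sd, spec.n_probes)
    truth = {
        "onemer_weights": w1.tolist(),
        "stacking_weights": ws.tolist(),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return ProbeSet(tuple(seqs), np.exp(ln_i), name="synthetic"), truth


@dataclass
class SnpCohortSpec:
    """Composition of a synthetic SNP cohort.

    ``planted_enrichment`` is the extra probability that an in-TFBS
    variant is redrawn uniformly from the high-|ddGs| (>= 0.6 kcal/mol)
    entries of the difference matrix.
    """

    n_snps: int = 1000
    type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    tfbs_fraction: float = 0.4
    planted_enrichment: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.type_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"type weights sum to {total}, expected 1")
        if not 0.0 <= self.planted_enrichment <= 1.0:
            raise ValueError("planted_enrichment must be in [0, 1]")
        if not 0.0 <= self.tfbs_fraction <= 1.0:
            raise ValueError("tfbs_fraction must be in [0, 1]")


def gen_snp_cohort(
    spec: SnpCohortSpec, dm: DifferenceMatrix
) -> list[SnpRecord]:
    """Draw SNP records with controlled type mix and optional planted bias.

    Contexts are uniform over the 16 flank combinations given the sampled
    mutation type; the planted redraw may change the mutation type (some
    types, e.g. G<->C, have no high-|ddGs| context at all).
    """
    rng = np.random.default_rng(spec.seed)
    types = list(spec.type_weights)
    weights = np.array([spec.type_weights[t] for t in types])
    weights = weights / weights.sum()
    high_entries = [
        (ctx, alt)
        for (ctx, alt), v in dm.substitutions().items()
        if abs_bin(v, DEFAULT_BINS) == "high"
    ]
    records: list[SnpRecord] = []
    for i in range(spec.n_snps):
        in_tfbs = bool(rng.random() < spec.tfbs_fraction)
        if (
            in_tfbs
            and spec.planted_enrichment > 0
            and rng.random() < spec.planted_enrichment
        ):
            ctx, alt = high_entries[rng.integers(len(high_entries))]
        else:
            mtype = types[rng.choice(len(types), p=weights)]
            ref, alt = mtype.split(">")
            ctx = (
                _BASES[rng.integers(4)] + ref + _BASES[rng.integers(4)]
            )
        records.append(
            SnpRecord(
                id=f"snp{i}", context=ctx, ref=ctx[1], alt=alt, in_tfbs=in_tfbs
            )
        )
    return records


def write_snp_tsv(records, path: str | Path) -> Path:
    """Write records in the dialect ``read_snp_table`` consumes."""
    path = Path(path)
    with open(path, "w") as out:
        for r in records:
            tfbs = "" if r.in_tfbs is None else int(r.in_tfbs)
            out.write(f"{r.id}\t{r.context}\t{r.ref}\t{r.alt}\t{tfbs}\n")
    return path


def gen_reference_with_snps(
    n_contigs: int = 2,
    contig_length: int = 300,
    n_snps: int = 20,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> tuple[Path, Path, list[dict]]:
    """Write a reference FASTA, a matching VCF and a context truth table.

    Variant positions are 1-based, interior-only (never at a contig end),
    at most one per site. Returns (fasta_path, vcf_path, truth).
    """
    if contig_length < 3:
        raise ValueError("contig_length must be >= 3")
    if n_snps > n_contigs * (contig_length - 2):
        raise ValueError("more SNPs requested than interior positions")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = {
        f"chr{i + 1}": gen_random_dna(
            1, contig_length, seed=int(rng.integers(2**31))
        )[0]
        for i in range(n_contigs)
    }
    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w") as fa:
        for name, seq in contigs.items():
            fa.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fa.write(seq[i : i + 60] + "\n")

    sites = [
        (name, pos) for name in contigs for pos in range(2, contig_length)
    ]  # 1-based interior positions
    pick = rng.choice(len(sites), size=n_snps, replace=False)
    chosen = sorted(sites[i] for i in pick)
    truth: list[dict] = []
    vcf_path = out_dir / "snps.vcf"
    with open(vcf_path, "w") as vcf:
        vcf.write("##fileformat=VCFv4.2\n")
        for name in contigs:
            vcf.write(f"##contig=<ID={name},length={contig_length}>\n")
        vcf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for j, (chrom, pos) in enumerate(chosen):
            seq = contigs[chrom]
            ref = seq[pos - 1]
            alt = rng.choice([b for b in DNA_BASES if b != ref])
            vcf.write(f"{chrom}\t{pos}\trs{j}\t{ref}\t{alt}\t.\tPASS\t.\n")
            truth.append(
                {
                    "id": f"rs{j}",
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": str(alt),
                    "context": seq[pos - 2 : pos + 1],
                }
            )
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return fasta_path, vcf_path, truth
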