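"""SNP annotation with stacking free-energy differences and cohort statistics.

Each biallelic substitution is placed in its wild-type trinucleotide
context (variant base central) and scored with ddGs from the difference
matrix. Cohorts are summarized by the |ddGs| bins 0.0-0.3, 0.3-0.6 and
>= 0.6 kcal/mol, by the 12 ordered mutation types, and by the fraction with
enhanced stacking (ddGs < 0). Enrichment of enhanced-stacking variants
inside TF binding sites is tested with the hypergeometric upper tail
(population = all annotated SNPs, successes = enhanced, sample = in-TFBS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from ._util import DNA_BASES, check_acgt, revcomp
from .energy import DifferenceMatrix

__all__ = [
    "SnpRecord",
    "SnpAnnotation",
    "CohortSummary",
    "DEFAULT_BINS",
    "MUTATION_TYPES",
    "extract_context",
    "annotate_snp",
    "abs_bin",
    "summarize_cohort",
    "matrix_background",
    "hypergeometric_enrichment",
    "compare_bin_series",
    "read_snp_table",
    "write_annotations",
]

logger = logging.getLogger(__name__)

#: |ddGs| bin edges (kcal/mol): [0, 0.3), [0.3, 0.6), [0.6, inf).
DEFAULT_BINS = (0.3, 0.6)
BIN_LABELS = ("low", "mid", "high")

MUTATION_TYPES = tuple(
    f"{r}>{a}" for r in DNA_BASES for a in DNA_BASES if r != a
)


@dataclass(frozen=True)
class SnpRecord:
    """One substitution with its wild-type trinucleotide context."""

    id: str
    context: str  # wild-type trimer, variant base central
    ref: str
    alt: str
    in_tfbs: bool | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        ctx = check_acgt(self.context, what=f"context of {self.id}")
        ref = check_acgt(self.ref, what=f"ref of {self.id}")
        alt = check_acgt(self.alt, what=f"alt of {self.id}")
        object.__setattr__(self, "context", ctx)
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if len(ctx) != 3 or len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"{self.id}: need a 3-mer context and single bases")
        if ctx[1] != ref:
            raise ValueError(
                f"{self.id}: context central base {ctx[1]} != ref {ref}"
            )
        if ref == alt:
            raise ValueError(f"{self.id}: ref and alt are identical")


@dataclass(frozen=True)
class SnpAnnotation:
    record: SnpRecord
    ddg: float  # kcal/mol, mutated minus wild type
    abs_bin: str  # low / mid / high
    mutation_type: str  # "R>A"
    enhanced: bool  # ddg < 0: stacking strengthened by the mutation


@dataclass(frozen=True)
class CohortSummary:
    n: int
    bin_fractions: tuple[float, float, float]  # percent, low/mid/high
    enhanced_fraction: float  # percent
    per_type: dict[str, tuple[float, float]]  # type -> (percent, mean |ddg|)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bin_fractions": dict(zip(BIN_LABELS, self.bin_fractions)),
            "enhanced_fraction": self.enhanced_fraction,
            "per_type": {
                t: {"percent": p, "mean_abs_ddg": m}
                for t, (p, m) in self.per_type.items()
            },
        }


def extract_context(chrom, pos, ref, alt, reference):
    """Pull the trinucleotide context around a 1-based VCF position.

    ``reference`` is a :class:`pyfaidx.Fasta` (or a path to a FASTA).
    Returns a :class:`SnpRecord`, or ``None`` (with a warning) for
    contig-edge positions or ambiguous bases in the context. A mismatch
    between ``ref`` and the reference base is an error.
    """
    import pyfaidx

    if not isinstance(reference, pyfaidx.Fasta):
        reference = pyfaidx.Fasta(str(reference))
    contig = reference[str(chrom)]
    if pos < 2 or pos > len(contig) - 1:
        warnings.warn(f"{chrom}:{pos}: no full trinucleotide context, skipped")
        return None
    context = str(contig[pos - 2 : pos + 1]).upper()
    if any(b not in DNA_BASES for b in context):
        warnings.warn(f"{chrom}:{pos}: ambiguous base in context {context}, skipped")
        return None
    ref = ref.upper()
    if context[1] != ref:
        raise ValueError(
            f"{chrom}:{pos}: reference has {context[1]} but record says {ref}"
        )
    return SnpRecord(id=f"{chrom}:{pos}", context=context, ref=ref, alt=alt.upper())


def abs_bin(ddg: float, bins: tuple[float, float] = DEFAULT_BINS) -> str:
    """Left-closed |ddGs| bin: values on an edge fall in the upper bin."""
    a = abs(ddg)
    if a < bins[0]:
        return "low"
    if a < bins[1]:
        return "mid"
    return "high"


def annotate_snp(
    record: SnpRecord,
    dm: DifferenceMatrix,
    bins: tuple[float, float] = DEFAULT_BINS,
) -> SnpAnnotation:
    """Score one SNP with ddGs and derive its bin / type / enhanced flag."""
    ddg = dm[(record.context, record.alt)]
    return SnpAnnotation(
        record=record,
        ddg=ddg,
        abs_bin=abs_bin(ddg, bins),
        mutation_type=f"{record.ref}>{record.alt}",
        enhanced=ddg < 0,
    )


def summarize_cohort(
    annotations: Sequence[SnpAnnotation],
    subset_filter: Callable[[SnpAnnotation], bool] | None = None,
) -> CohortSummary:
    """Bin fractions, enhanced fraction and per-type statistics of a cohort."""
    if subset_filter is not None:
        annotations = [a for a in annotations if subset_filter(a)]
    n = len(annotations)
    if n == 0:
        raise ValueError("empty cohort after filtering")
    bin_counts = {label: 0 for label in BIN_LABELS}
    enhanced = 0
    by_type: dict[str, list[float]] = {t: [] for t in MUTATION_TYPES}
    for a in annotations:
        bin_counts[a.abs_bin] += 1
        enhanced += a.enhanced
        by_type[a.mutation_type].append(abs(a.ddg))
    per_type = {
        t: (100.0 * len(v) / n, float(np.mean(v)) if v else 0.0)
        for t, v in by_type.items()
    }
    return CohortSummary(
        n=n,
        bin_fractions=tuple(100.0 * bin_counts[lab] / n for lab in BIN_LABELS),
        enhanced_fraction=100.0 * enhanced / n,
        per_type=per_type,
    )


def matrix_background(
    dm: DifferenceMatrix, bins: tuple[float, float] = DEFAULT_BINS
) -> tuple[float, float, float]:
    """|ddGs| bin percentages over the 192 non-identity matrix entries."""
    subs = list(dm.substitutions().values())
    counts = {label: 0 for label in BIN_LABELS}
    for v in subs:
        counts[abs_bin(v, bins)] += 1
    return tuple(100.0 * counts[lab] / len(subs) for lab in BIN_LABELS)


def hypergeometric_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    k = successes in the sample, n = sample size, K = successes in the
    population, N = population size.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def compare_bin_series(
    series_a: Sequence[float],
    series_b: Sequence[float],
    mode: str = "two-sample",
) -> tuple[float, float]:
    """Student's t comparison of two equal-length series.

    ``mode='two-sample'`` treats the series as independent samples
    (equal-variance t test); ``mode='paired'`` pairs them bin by bin. Both
    are offered because either framing is defensible for per-bin
    percentage series. Returns (statistic, two-sided p).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if mode == "paired":
        if np.all(a == b):
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
    elif mode == "two-sample":
        if a.std() == 0.0 and b.std() == 0.0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            raise ValueError("both series have zero variance")
        t, p = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(t), float(p)


def _parse_tsv_row(parts: list[str], lineno: int) -> SnpRecord:
    if len(parts) < 4:
        raise ValueError(f"line {lineno}: expected >= 4 columns")
    in_tfbs = None
    pvalue = None
    if len(parts) >= 5 and parts[4] != "":
        in_tfbs = bool(int(parts[4]))
    if len(parts) >= 6 and parts[5] != "":
        pvalue = float(parts[5])
    return SnpRecord(
        id=parts[0],
        context=parts[1],
        ref=parts[2],
        alt=parts[3],
        in_tfbs=in_tfbs,
        pvalue=pvalue,
    )


def read_snp_table(
    path: str | Path,
    format: str = "tsv",
    reference: str | Path | None = None,
    max_pvalue: float | None = None,
) -> list[SnpRecord]:
    """Read SNP records from a context TSV or a VCF (+ reference FASTA).

    TSV columns: ``id  context  ref  alt  [in_tfbs(0/1)]  [pvalue]``, no
    header, ``#`` comments. VCF mode keeps biallelic SNVs only and
    extracts contexts from ``reference``. Malformed / unusable rows are
    logged and skipped; more than 50% skipped is a hard error.
    ``max_pvalue`` optionally applies a significance filter (TSV pvalue
    column only).
    """
    path = Path(path)
    records: list[SnpRecord] = []
    skipped = 0
    total = 0
    if format == "tsv":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            total += 1
            try:
                rec = _parse_tsv_row(line.split("\t"), lineno)
            except (ValueError, KeyError) as exc:
                logger.warning("%s:%d skipped: %s", path, lineno, exc)
                skipped += 1
                continue
            if (
                max_pvalue is not None
                and rec.pvalue is not None
                and rec.pvalue > max_pvalue
            ):
                continue
            records.append(rec)
    elif format == "vcf":
        if reference is None:
            raise ValueError("VCF input requires a reference FASTA")
        import pyfaidx
        from cyvcf2 import VCF

        fasta = pyfaidx.Fasta(str(reference))
        for variant in VCF(str(path)):
            total += 1
            alts = variant.ALT
            if (
                len(alts) != 1
                or len(variant.REF) != 1
                or len(alts[0]) != 1
                or variant.REF not in DNA_BASES
                or alts[0] not in DNA_BASES
            ):
                logger.warning(
                    "%s:%s not a biallelic SNV, skipped", variant.CHROM, variant.POS
                )
                skipped += 1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                rec = extract_context(
                    variant.CHROM, variant.POS, variant.REF, alts[0], fasta
                )
            if rec is None:
                skipped += 1
                continue
            rid = variant.ID or rec.id
            records.append(
                SnpRecord(rid, rec.context, rec.ref, rec.alt)
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    if total and skipped > 0.5 * total:
        raise ValueError(
            f"{path}: {skipped}/{total} rows skipped; input looks malformed"
        )
    if skipped:
        logger.info("%s: skipped %d/%d rows", path, skipped, total)
    return records


def write_annotations(
    annotations: Iterable[SnpAnnotation], path: str | Path
) -> Path:
    """Annotation TSV mirroring the input plus derived columns."""
    path = Path(path)
    with open(path, "w") as out:
        out.write(
            "id\tcontext\tref\talt\tin_tfbs\tpvalue\t"
            "ddg\tabs_bin\tmutation_type\tenhanced\n"
        )
        for a in annotations:
            r = a.record
            tfbs = "" if r.in_tfbs is None else int(r.in_tfbs)
            pval = "" if r.pvalue is None else repr(r.pvalue)
            out.write(
                f"{r.id}\t{r.context}\t{r.ref}\t{r.alt}\t{tfbs}\t{pval}\t"
                f"{a.ddg:.6g}\t{a.abs_bin}\t{a.mutation_type}\t{int(a.enhanced)}\n"
            )
    return path
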