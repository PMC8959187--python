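"""End-to-end CNV calling pipeline and call output formats (TSV, VCF)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .coverage import CoverageMatrix
from .errors import ErrorMatrix, estimate_errors
from .hmm import (
    DEL,
    DUP,
    NORM,
    CnvCall,
    Emissions,
    HmmConfig,
    emissions,
    segment_calls,
    viterbi_batch,
)
from .normalize import DosageMatrix, normalize_dosage, select_active_bins, svd_denoise

__all__ = ["call_cnvs", "calls_to_frame", "write_calls_tsv", "write_calls_vcf"]

_P_MIN = 1e-300


def call_cnvs(
    counts: CoverageMatrix,
    *,
    n_discard: int = 5,
    transition_prob: float = 1e-5,
    mosaic: bool = False,
    min_quality: float = 0.0,
    min_mean_count: float = 1.0,
    error_model: str = "multiplicative",
    return_intermediates: bool = False,
):
    """Call deletions and duplications for every sample of a cohort.

    Pipeline: active-bin selection -> two-step normalization -> SVD
    denoising (``n_discard`` components) -> error estimation -> tail-
    probability emissions -> per-chromosome Viterbi -> segmentation and
    phred-like scoring -> quality filter.  Deterministic given inputs and
    parameters.

    Returns a list of `CnvCall` sorted by (sample, chromosome, start); with
    ``return_intermediates=True`` also returns the `DosageMatrix` and
    `ErrorMatrix` for inspection.
    """
    if counts.n_samples < 3:
        raise ValueError("CNV calling needs at least 3 samples")
    mask = select_active_bins(counts, min_mean_count=min_mean_count)
    d_norm = normalize_dosage(counts, mask)
    d = d_norm
    rank_budget = min(d.dosage.shape) - 1
    if n_discard > rank_budget:
        warnings.warn(
            f"cohort supports discarding at most {rank_budget} singular "
            f"vectors; reducing n_discard from {n_discard}"
        )
        n_discard = rank_budget
    d = svd_denoise(d, n_discard=n_discard)
    err = estimate_errors(d, counts, model=error_model)
    config = HmmConfig(transition_prob=transition_prob, mosaic=mosaic)
    # detect on the denoised dosage, but quantify mean_dosage from the
    # pre-denoising matrix: removing singular components shrinks true event
    # amplitude toward 1, while the normalized dosage is unbiased
    calls = _call_from_dosage(d, err, config, min_quality, quant_dosage=d_norm.dosage)
    if return_intermediates:
        return calls, d, err
    return calls


def _call_from_dosage(
    d: DosageMatrix,
    err: ErrorMatrix,
    config: HmmConfig,
    min_quality: float,
    quant_dosage: np.ndarray | None = None,
) -> list[CnvCall]:
    em: Emissions = emissions(d.dosage, err.sigma, mosaic=config.mosaic)
    log_p = em.log_stacked()  # samples x active bins x 3
    if quant_dosage is None:
        quant_dosage = d.dosage
    binning = d.binning
    active_idx = d.active_indices
    calls: list[CnvCall] = []
    for chrom in binning.chrom_names:
        sl = binning.chrom_slice(chrom)
        in_chrom = (active_idx >= sl.start) & (active_idx < sl.stop)
        cols = np.flatnonzero(in_chrom)
        if cols.size == 0:
            continue
        bin_starts = binning.starts[active_idx[cols]]
        bin_ends = binning.ends[active_idx[cols]]
        paths = viterbi_batch(log_p[:, cols, :], config, log=True)
        for s, sample_id in enumerate(d.sample_ids):
            path = paths[s]
            if np.all(path == NORM):
                continue
            # per-bin evidence for whichever CNV state the path is in
            state_lp = np.where(path == DEL, log_p[s, cols, DEL], log_p[s, cols, DUP])
            log_ratio = state_lp - log_p[s, cols, NORM]
            calls.extend(
                segment_calls(
                    path,
                    quant_dosage[s, cols],
                    log_ratio,
                    bin_starts,
                    bin_ends,
                    chrom,
                    sample_id,
                )
            )
    calls = [c for c in calls if c.quality >= min_quality]
    order = {name: i for i, name in enumerate(binning.chrom_names)}
    calls.sort(key=lambda c: (c.sample_id, order[c.chrom], c.start))
    return calls


_CALL_COLUMNS = ["chrom", "start", "end", "sample", "type", "n_bins", "mean_dosage", "quality"]


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    """Calls as a BED-compatible DataFrame (first three columns chrom/start/end)."""
    return pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.sample_id, c.type, c.n_bins, c.mean_dosage, c.quality)
            for c in calls
        ],
        columns=_CALL_COLUMNS,
    )


def write_calls_tsv(calls: list[CnvCall], path) -> None:
    df = calls_to_frame(calls)
    df["mean_dosage"] = df["mean_dosage"].map(lambda v: f"{v:.4f}")
    df["quality"] = df["quality"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        CnvCall(
            sample_id=str(r["sample"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            type=str(r["type"]),
            n_bins=int(r["n_bins"]),
            mean_dosage=float(r["mean_dosage"]),
            quality=float(r["quality"]),
        )
        for _, r in df.iterrows()
    ]


def write_calls_vcf(calls: list[CnvCall], binning, path) -> None:
    """Write calls as VCF 4.2 with symbolic <DEL>/<DUP> alleles.

    One sample column per distinct sample; FORMAT CN reports the copy number
    under the default diploid assumption (1 for DEL, 3 for DUP); QUAL is the
    phred-like call quality; INFO carries END and SVLEN.  POS is the padding
    base before the event, per the usual symbolic-allele convention, so
    END = POS + |SVLEN| lands on the event's last base (for an event at the
    very start of a chromosome there is no padding base and END overshoots
    by one).
    """
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line(f'##source=depthcnv-{__version__}')
    for name, length in binning.chromosomes:
        header.contigs.add(name, length=length)
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=DUP,Description="Duplication">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">')
    samples = sorted({c.sample_id for c in calls})
    for s in samples:
        header.add_sample(s)
    order = {name: i for i, name in enumerate(binning.chrom_names)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (order[c.chrom], c.start, c.sample_id)):
            rec = vcf.new_record(
                contig=c.chrom,
                start=max(c.start - 1, 0),
                stop=c.end,
                alleles=("N", f"<{c.type}>"),
            )
            rec.qual = c.quality
            rec.info["SVTYPE"] = c.type
            rec.info["SVLEN"] = c.size if c.type == "DUP" else -c.size
            for s in samples:
                if s == c.sample_id:
                    rec.samples[s]["GT"] = (0, 1)
                    rec.samples[s]["CN"] = 1 if c.type == "DEL" else 3
                else:
                    rec.samples[s]["GT"] = (None,)
            vcf.write(rec)
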