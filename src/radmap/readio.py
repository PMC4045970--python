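"""Demultiplexing, tag trimming, and the read quality filter.

Barcoded single-end reads are assigned to samples by exact barcode
prefix match, trimmed to a fixed 92-base tag (removing the 4-8 bp inline
barcode), and dropped when five or more bases fall below Q20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .simcross import FastqRead

TAG_LENGTH = 92
MIN_Q = 20
MAX_LOW_Q = 4  # allowed sub-MIN_Q bases; one more means drop


@dataclass
class SampleReadSet:
    """Retained 92-base tags for one sample plus the filter accounting."""

    sample_id: str
    tags: list[FastqRead] = field(default_factory=list)
    n_raw: int = 0
    n_low_quality: int = 0
    n_too_short: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.tags)


@dataclass
class DemuxResult:
    samples: dict[str, SampleReadSet]
    n_total: int = 0
    n_ambiguous: int = 0

    def counts_frame(self):
        import pandas as pd

        rows = [
            (s.sample_id, s.n_raw, s.n_low_quality, s.n_too_short, s.n_retained)
            for s in self.samples.values()
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "raw", "low_quality", "too_short", "retained"]
        )


def read_barcode_table(path: str | Path) -> dict[str, str]:
    barcodes = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0] == "sample_id":
                continue
            barcodes[parts[0]] = parts[1]
    return barcodes


def validate_barcodes(barcodes: dict[str, str]) -> None:
    seen: dict[str, str] = {}
    for sample, bc in barcodes.items():
        if not 4 <= len(bc) <= 8:
            raise ValueError(f"barcode for {sample} not 4-8 bp: {bc}")
        if bc in seen:
            raise ValueError(f"duplicate barcode {bc} ({seen[bc]}, {sample})")
        seen[bc] = sample


def trim_tag(sequence: str, quality: str, tag_length: int = TAG_LENGTH):
    """First ``tag_length`` bases of the post-barcode read, or None when
    the remainder is shorter than the tag."""
    if len(sequence) < tag_length:
        return None
    return sequence[:tag_length], quality[:tag_length]


def quality_ok(quality: str, min_q: int = MIN_Q, max_low_q: int = MAX_LOW_Q) -> bool:
    """Keep unless the number of bases below ``min_q`` exceeds
    ``max_low_q`` (i.e. drop at >= 5 sub-Q20 bases by default)."""
    cutoff = chr(min_q + 33)
    low = sum(1 for c in quality if c < cutoff)
    return low <= max_low_q


def demultiplex(
    reads,
    barcodes: dict[str, str],
    tag_length: int = TAG_LENGTH,
    min_q: int = MIN_Q,
    max_low_q: int = MAX_LOW_Q,
) -> DemuxResult:
    """Assign reads to samples by exact barcode prefix, strip the barcode,
    trim to the tag length and apply the quality filter.

    Reads matching no barcode are counted as ambiguous and dropped.
    Count conservation: raw = retained + low_quality + too_short per
    sample, and total = ambiguous + sum(raw).
    """
    validate_barcodes(barcodes)
    by_prefix = {bc: sid for sid, bc in barcodes.items()}
    lengths = sorted({len(bc) for bc in by_prefix}, reverse=True)
    result = DemuxResult(
        samples={sid: SampleReadSet(sample_id=sid) for sid in barcodes}
    )
    for read in reads:
        result.n_total += 1
        sample_id = None
        for n in lengths:
            sid = by_prefix.get(read.sequence[:n])
            if sid is not None:
                sample_id = sid
                barcode_len = n
                break
        if sample_id is None:
            result.n_ambiguous += 1
            continue
        sample = result.samples[sample_id]
        sample.n_raw += 1
        seq = read.sequence[barcode_len:]
        qual = read.quality[barcode_len:]
        trimmed = trim_tag(seq, qual, tag_length)
        if trimmed is None:
            sample.n_too_short += 1
            continue
        seq, qual = trimmed
        if not quality_ok(qual, min_q, max_low_q):
            sample.n_low_quality += 1
            continue
        sample.tags.append(FastqRead(read.read_id, seq, qual))
    return result


def read_fastq(path: str | Path):
    """Iterate FASTQ records as FastqRead (four-line records, Phred+33)."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield FastqRead(header[1:].split()[0], seq, qual)


def write_sample_fastq(result: DemuxResult, outdir: str | Path) -> None:
    from .simcross import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, sample in result.samples.items():
        write_fastq(sample.tags, outdir / f"{sid}.tags.fastq")
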