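from rosyn.intervals import GenomicInterval, Peak


def make_peaks(spans: list[tuple[int, int]], chrom: str = "chr1") -> list[Peak]:
    return [
        Peak(GenomicInterval(chrom, s, e), f"p{i}") for i, (s, e) in enumerate(spans)
    ]
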