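"""Independent brute-force oracles used to cross-check the pipeline.

These are deliberately written as naive, direct transcriptions of the
filtering boolean and of pairwise interval overlap, sharing no code with
the package's own engines.
"""

from __future__ import annotations

import random

from ipsmut.io import GenomicInterval, SampleCall, VariantRecord


def oracle_keep(record: VariantRecord, sample: str) -> bool:
    """Naive re-evaluation of the full printed filter boolean."""
    call = record.calls[sample]
    qual = record.qual
    qd = record.info.get("QD")
    mq = record.info.get("MQ")
    fs = record.info.get("FS")
    hs = record.info.get("HaplotypeScore")
    gq = call.gq
    if any(v is None for v in (qual, qd, mq, fs, hs, gq)):
        return False
    if qual < 400 or qd < 2.0 or mq < 40.0 or fs > 60.0 or hs > 13.0 or gq <= 60:
        return False
    gt, ad = call.genotype, call.allelic_depths
    if gt is None or ad is None:
        return False
    i, j = gt
    if i != j:
        a, b = ad[i], ad[j]
        return a >= 8 and b >= 8 and max(a, b) <= 2 * min(a, b)
    a = ad[i]
    b = max(d for k, d in enumerate(ad) if k != i)
    return (b > 0 and a >= 32 * b) or (b == 1 and a >= 16) or (b == 0 and a >= 8)


def oracle_overlaps(record: VariantRecord, interval: GenomicInterval) -> bool:
    """Base-by-base overlap: does the 0-based base pos-1 lie in [start, end)?"""
    if record.chrom != interval.chrom:
        return False
    return interval.start <= record.pos - 1 < interval.end


def random_records(n: int, seed: int, sample: str = "S1") -> list[VariantRecord]:
    """Diverse random records spanning pass/fail/missing space."""
    rng = random.Random(seed)
    out: list[VariantRecord] = []
    for k in range(n):
        n_alts = rng.choice([1, 1, 1, 2])
        alleles = rng.sample(["A", "C", "G", "T"], 1 + n_alts)
        n_alleles = 1 + n_alts

        def maybe(value):
            return None if rng.random() < 0.08 else value

        qual = maybe(rng.choice([rng.uniform(0, 399), 400.0,
                                 rng.uniform(401, 3000)]))
        info = {
            "QD": maybe(rng.choice([rng.uniform(0, 1.99), 2.0,
                                    rng.uniform(2.1, 35)])),
            "MQ": maybe(rng.choice([rng.uniform(0, 39.9), 40.0,
                                    rng.uniform(40.1, 70)])),
            "FS": maybe(rng.choice([rng.uniform(0, 59.9), 60.0,
                                    rng.uniform(60.1, 300)])),
            "HaplotypeScore": maybe(rng.choice([rng.uniform(0, 12.9), 13.0,
                                                rng.uniform(13.1, 50)])),
        }
        if rng.random() < 0.05:
            genotype = None
        else:
            genotype = tuple(sorted(rng.choices(range(n_alleles), k=2)))
        if rng.random() < 0.05:
            depths = None
        else:
            depths = tuple(
                rng.choice([0, 1, rng.randint(2, 7), rng.randint(8, 20),
                            rng.randint(21, 200)])
                for _ in range(n_alleles)
            )
        gq = maybe(rng.choice([rng.randint(0, 59), 60, 61,
                               rng.randint(62, 99)]))
        call = SampleCall(genotype=genotype, allelic_depths=depths, gq=gq)
        out.append(
            VariantRecord(
                chrom=f"chr{rng.randint(1, 3)}",
                pos=k + 1,
                ref=alleles[0],
                alts=tuple(alleles[1:]),
                qual=qual,
                info=info,
                calls={sample: call},
            )
        )
    return out
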