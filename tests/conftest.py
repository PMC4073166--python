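from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from ipsmut.io import SampleCall, VariantRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(
    chrom: str = "chr1",
    pos: int = 100,
    ref: str = "A",
    alts: tuple[str, ...] = ("G",),
    qual: float | None = 1000.0,
    qd: float | None = 20.0,
    mq: float | None = 60.0,
    fs: float | None = 1.0,
    hs: float | None = 1.0,
    calls: dict[str, SampleCall] | None = None,
) -> VariantRecord:
    """A record that passes every site clause unless overridden."""
    if calls is None:
        calls = {
            "S1": SampleCall(genotype=(0, 1), allelic_depths=(40, 40), gq=99)
        }
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=alts,
        qual=qual,
        info={"QD": qd, "MQ": mq, "FS": fs, "HaplotypeScore": hs},
        calls=calls,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def paper_scenario():
    """One shared study-like fixture bundle (seeded, deterministic)."""
    from ipsmut.synth import scenario_paper

    return scenario_paper(seed=20140627)
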