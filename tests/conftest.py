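import numpy as np
import pytest

from chargescan import (
    ChargeCluster,
    Polarity,
    ProteinRecord,
    ScanConfig,
)


@pytest.fixture
def fixed_config():
    """Scan configuration with a fixed background, the detector defaults."""
    return ScanConfig(
        window_w=20,
        alpha=1e-5,
        background_mode="fixed",
        fixed_p0_pos=0.05,
        fixed_p0_neg=0.05,
    )


@pytest.fixture
def planted_record():
    """One protein with an unambiguous 12-residue positive run."""
    return ProteinRecord(id="P1", sequence="A" * 10 + "K" * 12 + "A" * 10)


def make_cluster(
    protein_id="P1",
    polarity=Polarity.POSITIVE,
    start=11,
    end=22,
    sequence=None,
    **kwargs,
):
    length = end - start + 1
    if sequence is None:
        sequence = ("K" if polarity is Polarity.POSITIVE else "D") * length
    defaults = dict(
        charged_count=sum(
            ch in ("KR" if polarity is Polarity.POSITIVE else "DE") for ch in sequence
        ),
        net_charge=sum(ch in "KR" for ch in sequence) - sum(ch in "DE" for ch in sequence),
        min_window_p=1e-7,
    )
    defaults.update(kwargs)
    return ChargeCluster(
        protein_id=protein_id,
        polarity=polarity,
        start=start,
        end=end,
        sequence=sequence,
        **defaults,
    )


def random_sequence(rng: np.random.Generator, length: int, p_pos: float, p_neg: float) -> str:
    """Random sequence with given positive/negative class frequencies."""
    other = "ACFGHILMNPQSTVWY"
    draws = rng.random(length)
    out = []
    for u in draws:
        if u < p_pos:
            out.append("K" if rng.random() < 0.5 else "R")
        elif u < p_pos + p_neg:
            out.append("D" if rng.random() < 0.5 else "E")
        else:
            out.append(other[rng.integers(len(other))])
    return "".join(out)
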