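import numpy as np
import pytest
from hypothesis import settings

from blinkpipe.core import (
    Group,
    NormalizedTrial,
    RawTrial,
    TrialMeta,
    TrialType,
)
from blinkpipe.simulate import alpha_kernel

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

RATE = 1000.0
N_PRE = 500
N_POST = 1101  # 1100 ms after CS onset inclusive


def make_meta(
    day: int = 9,
    trial_type: TrialType = TrialType.CS_ONLY,
    mouse_id: str = "m01",
    group: Group = Group.STANDARD,
    trial_index: int = 1,
    block: int = 1,
):
    isi = 250 if day <= 10 else 500
    return TrialMeta(
        mouse_id=mouse_id,
        group=group,
        day=day,
        block=block,
        trial_index=trial_index,
        trial_type=trial_type,
        isi_ms=isi,
        cs_duration_ms=isi + 30,
    )


def make_raw(samples=None, meta=None, rate: float = RATE, **meta_kw) -> RawTrial:
    if meta is None:
        meta = make_meta(**meta_kw)
    if samples is None:
        samples = np.zeros(N_PRE + N_POST)
    return RawTrial(
        meta=meta,
        samples=np.asarray(samples, dtype=float),
        sample_rate_hz=rate,
        cs_onset_index=N_PRE,
        pre_cs_ms=500.0,
    )


def make_normalized(samples, meta=None, valid: bool = True, **meta_kw):
    if meta is None:
        meta = make_meta(**meta_kw)
    return NormalizedTrial(
        meta=meta,
        samples=np.asarray(samples, dtype=float),
        sample_rate_hz=RATE,
        cs_onset_index=N_PRE,
        valid=valid,
        rejection_reason=None if valid else "pre_cs_activity",
    )


def cr_trace(
    amplitude: float,
    onset_ms: float,
    peak_ms: float,
    noise_sd: float = 0.0,
    rng=None,
    n_pre: int = N_PRE,
    n_post: int = N_POST,
) -> np.ndarray:
    """Normalized-scale trace holding one synthetic CR."""
    t_ms = np.arange(-n_pre, n_post, dtype=float)
    y = amplitude * alpha_kernel(t_ms, onset_ms, peak_ms)
    if noise_sd > 0:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise_sd, y.size)
    return y


@pytest.fixture
def rng():
    return np.random.default_rng(20240312)
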