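import numpy as np
import pytest

from corticotroph.events import Trace

FS = 10_000.0
BASELINE = -51.0


def make_flat_trace(duration_s: float = 2.0, level: float = BASELINE,
                    fs: float = FS) -> Trace:
    n = int(duration_s * fs)
    return Trace(v_mv=np.full(n, level), fs_hz=fs)


def add_triangle(v: np.ndarray, fs: float, t_start: float, base_ms: float,
                 peak_delta: float) -> None:
    """Symmetric triangular excursion of given base width, in place."""
    n = int(base_ms * 1e-3 * fs)
    i0 = int(t_start * fs)
    half = n // 2
    up = np.linspace(0.0, peak_delta, half, endpoint=False)
    down = np.linspace(peak_delta, 0.0, n - half)
    v[i0:i0 + half] += up
    v[i0 + half:i0 + n] += down


@pytest.fixture
def flat_trace() -> Trace:
    return make_flat_trace()


@pytest.fixture
def triangle_trace() -> Trace:
    """One 40 ms triangular event from -51 to -20 mV at t = 1 s."""
    tr = make_flat_trace(3.0)
    add_triangle(tr.v_mv, FS, 1.0, 40.0, 31.0)
    return tr
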