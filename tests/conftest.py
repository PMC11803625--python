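import numpy as np
import pytest

from protoneuro import CircuitParams, CVSpec, PhaseSpec, gen_spike_trace, gen_voltammogram


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def clean_cv():
    """Noiseless 100-cycle voltammogram with the reference peak layout."""
    return gen_voltammogram(CVSpec(alpha=0.01, n_cycles=100, noise_sd=0.0), seed=1)


@pytest.fixture
def clean_spike_trace():
    """Noiseless spiking trace with ground-truth spike metadata attached."""
    phases = [PhaseSpec(0.0, 10_000.0, spike_rate=1.8, amp_mean=12.0,
                        amp_sd=2.0, noise_sd=0.0),
              # quiet tail so the last spike's decay is fully contained in
              # the recording (a truncated decay hides its true prominence)
              PhaseSpec(10_000.0, 10_300.0, spike_rate=0.0, amp_mean=12.0,
                        amp_sd=2.0, noise_sd=0.0)]
    return gen_spike_trace(phases, dt=1.0, seed=7, refractory=20.0)


@pytest.fixture
def reference_circuit():
    return CircuitParams()


@pytest.fixture
def trace_csv(tmp_path):
    """Minimal well-formed trace file on disk."""
    p = tmp_path / "trace.csv"
    p.write_text("time,potential\n0,1.0\n1,2.0\n2,1.5\n")
    return p
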