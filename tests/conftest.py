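import numpy as np
import pytest

from bpsr.lif import LayerParams


def make_random_layer(
    rng: np.random.Generator,
    n_in: int,
    n_out: int,
    kind: str = "recurrent",
    u_th: float = 1.0,
) -> LayerParams:
    """Random clamped layer for oracle comparisons."""
    w_in = rng.uniform(-u_th, u_th, (n_out, n_in))
    if kind == "recurrent":
        w_rec = rng.uniform(-u_th, u_th, (n_out, n_out))
        np.fill_diagonal(w_rec, 0.0)
        mask_rec = ~np.eye(n_out, dtype=bool)
    else:
        w_rec = np.zeros((n_out, n_out))
        mask_rec = np.zeros((n_out, n_out), dtype=bool)
    return LayerParams(
        w_in=w_in,
        w_rec=w_rec,
        bias=rng.uniform(-0.5, 0.9, n_out),
        tau=rng.uniform(0.0, 1.0, n_out),
        u_th=u_th,
        mask_in=np.ones((n_out, n_in), dtype=bool),
        mask_rec=mask_rec,
        coords=rng.uniform(size=(n_out, 3)),
        kind=kind,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
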