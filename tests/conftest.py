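import numpy as np
import pytest

from rxndkl.featurize import morgan_reaction_fp
from rxndkl.synthetic import GridSpec, synth_reaction_grid


@pytest.fixture(scope="session")
def small_grid():
    """A 4x3x2x4 synthetic reaction grid (96 reactions) with interactions."""
    spec = GridSpec(counts=(4, 3, 2, 4), interaction_strength=15.0, noise_sd=3.0, seed=7)
    return synth_reaction_grid(spec)


@pytest.fixture(scope="session")
def small_grid_features(small_grid):
    """Compact Morgan features (64 bits/component) of the small grid."""
    X = morgan_reaction_fp(small_grid, bits_per_component=64).values
    y = np.array([r.yield_ for r in small_grid])
    return X, y


def gradcheck(build, arrays, eps: float = 1e-6, tol: float = 1e-5) -> float:
    """Compare autodiff gradients of scalar `build(*tensors)` to central differences.

    Returns the worst relative error over all inputs; asserts it is < tol.
    """
    import rxndkl.autodiff as ad

    tensors = [ad.Tensor(a, requires_grad=True) for a in arrays]
    out = build(*tensors)
    out.backward()
    worst = 0.0
    for t, a in zip(tensors, arrays):
        num = np.zeros_like(a, dtype=float)
        it = np.nditer(a, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            up, down = a.copy(), a.copy()
            up[i] += eps
            down[i] -= eps
            f_up = build(*[ad.Tensor(up if t2 is t else b) for t2, b in zip(tensors, arrays)]).value
            f_dn = build(*[ad.Tensor(down if t2 is t else b) for t2, b in zip(tensors, arrays)]).value
            num[i] = (f_up - f_dn) / (2 * eps)
        err = float(np.abs(num - t.grad).max() / max(1.0, np.abs(num).max()))
        worst = max(worst, err)
    assert worst < tol, f"gradient mismatch: {worst:.3e}"
    return worst
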