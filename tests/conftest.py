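import numpy as np
import pytest

from patchnoise import GradientKernels


@pytest.fixture
def diff_kernels():
    return GradientKernels.first_difference()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def eps_bruteforce(patch: np.ndarray, kernels: GradientKernels) -> float:
    """Independent double-loop evaluation of the gradient texture intensity."""
    patch = np.asarray(patch, dtype=np.float64)
    total = 0.0
    for kernel in (kernels.hh, kernels.hv):
        kh, kw = kernel.shape
        for i in range(patch.shape[0] - kh + 1):
            for j in range(patch.shape[1] - kw + 1):
                acc = 0.0
                for a in range(kh):
                    for b in range(kw):
                        acc += kernel[a, b] * patch[i + a, j + b]
                total += abs(acc)
    return total
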