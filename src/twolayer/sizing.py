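"""Closed-form hidden-layer sizing for two-hidden-layer classifiers.

Huang's learnability result gives explicit hidden-layer widths that are
sufficient for a two-hidden-layer feedforward network to learn ``N``
distinct samples with ``m`` output neurons:

    layer 1:  sqrt((m + 2) * N) + 2 * sqrt(N / (m + 2))
    layer 2:  m * sqrt(N / (m + 2))

Raw sizes are real numbers; practical layer widths round them up to whole
neurons (ceiling).  For the six-category joystick problem (N = 5400,
m = 6) this yields 259.81 -> 260 and 155.88 -> 156 neurons.
"""

from __future__ import annotations

import math


def _validate(n_samples: int, n_outputs: int) -> None:
    for name, value in (("n_samples", n_samples), ("n_outputs", n_outputs)):
        if not float(value).is_integer() or value < 1:
            raise ValueError(f"{name} must be a positive integer, got {value!r}")


def huang_raw_sizes(n_samples: int, n_outputs: int) -> tuple[float, float]:
    """Raw (un-rounded) hidden-layer sizes for N samples and m outputs.

    Parameters
    ----------
    n_samples:
        Number of distinct training samples, N >= 1.
    n_outputs:
        Number of output neurons (classes), m >= 1.

    Returns
    -------
    (layer1_raw, layer2_raw):
        Positive reals; ``layer1_raw = sqrt((m+2)N) + 2 sqrt(N/(m+2))``
        and ``layer2_raw = m sqrt(N/(m+2))``.
    """
    _validate(n_samples, n_outputs)
    n = float(n_samples)
    m = float(n_outputs)
    ratio = math.sqrt(n / (m + 2.0))
    layer1 = math.sqrt((m + 2.0) * n) + 2.0 * ratio
    layer2 = m * ratio
    return layer1, layer2


def huang_layer_sizes(n_samples: int, n_outputs: int) -> tuple[int, int]:
    """Whole-neuron hidden-layer sizes: ceiling of the raw sizes."""
    layer1, layer2 = huang_raw_sizes(n_samples, n_outputs)
    return math.ceil(layer1), math.ceil(layer2)
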