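"""The three layer families and their correctness oracles.

Runs a bidirectional selective-SSM scan against its sequential oracle, an
FFT long convolution against direct convolution, and chunked attention
against dense attention, printing the maximum deviations — the same
equivalences the test suite enforces.
"""

import numpy as np

from seq2cov import ssm
from seq2cov.attention import chunked_attention, dense_attention
from seq2cov.convnet import compose_dilated_kernels, fft_long_conv, _dilate

rng = np.random.default_rng(0)

# selective-SSM: associative parallel scan vs sequential recurrence
L, D, N = 512, 4, 8
A = -rng.uniform(0.05, 2.0, (D, N))
delta = rng.uniform(1e-3, 0.3, (L, D))
B, C = rng.standard_normal((2, L, N))
x = rng.standard_normal((L, D))
Ab, Bb = ssm.discretize(A, B, delta)
d = np.abs(ssm.ssm_scan_sequential(x, Ab, Bb, C)
           - ssm.ssm_scan_associative(x, Ab, Bb, C)).max()
print(f"scan: parallel vs sequential max |diff| = {d:.2e}  (same recurrence)")

# FFT long convolution vs direct O(L^2) convolution
xs = rng.standard_normal((257, 1))
k = rng.standard_normal((257, 1))
y = fft_long_conv(xs, k, causal=False)
full = np.convolve(xs[:, 0], k[:, 0])
d = np.abs(y[:, 0] - full[128:128 + 257]).max()
print(f"fft long conv vs direct: max |diff| = {d:.2e}")

# serial dilated convolutions collapse into one long kernel
k1, k2 = rng.standard_normal(3), rng.standard_normal(3)
composed = compose_dilated_kernels([k1, k2], [1, 2])
sig = rng.standard_normal(100)
serial = np.convolve(np.convolve(sig, k1), _dilate(k2, 2))
d = np.abs(np.convolve(sig, composed) - serial).max()
print(f"composed dilated kernel (width {composed.size}) vs serial: {d:.2e}")

# chunked (flash-style) attention vs dense softmax attention
q, kk = rng.standard_normal((2, 100, 16))
v = rng.standard_normal((100, 8))
dense = dense_attention(q, kk, v)
for chunk in (1, 7, 64):
    d = np.abs(chunked_attention(q, kk, v, chunk) - dense).max()
    print(f"chunked attention (chunk={chunk}) vs dense: {d:.2e}")
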