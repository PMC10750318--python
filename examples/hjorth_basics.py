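"""Compute the three Hjorth parameters and compare with analytic values.

A sampled sinusoid at frequency f has activity A^2/2 (amplitude A),
mobility 2*sin(pi*f/fs) and complexity 1; broadband white noise tends to
mobility sqrt(2) and complexity sqrt(3/2).
"""

import math

import numpy as np

from hjortheeg import hjorth_triple

fs, n = 125.0, 500
sine = 3.0 * np.sin(2 * np.pi * 10 * np.arange(n) / fs)
triple = hjorth_triple(sine)
print("10 Hz sine, amplitude 3 uV, fs = 125 Hz:")
print(f"  activity   = {triple.activity:.4f} uV^2   (analytic 3^2/2 = {4.5})")
print(f"  mobility   = {triple.mobility:.5f}        (analytic 2 sin(pi f/fs) = {2 * math.sin(math.pi * 10 / fs):.5f})")
print(f"  complexity = {triple.complexity:.5f}        (analytic 1 for a pure sinusoid)")

noise = np.random.default_rng(0).standard_normal(100_000)
triple = hjorth_triple(noise)
print("white Gaussian noise, n = 100000:")
print(f"  mobility   = {triple.mobility:.5f}        (limit sqrt(2)  = {math.sqrt(2):.5f})")
print(f"  complexity = {triple.complexity:.5f}        (limit sqrt(3/2) = {math.sqrt(1.5):.5f})")
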