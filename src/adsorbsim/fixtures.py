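"""Deterministic synthetic-data generator for tests and demos.

Every fixture is a small CSV whose header comments embed the full parameter
set, the seed, and the ground truth, so a file documents how to reproduce
itself.  Same seed, same bytes.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from . import kinetics

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("exponential_trace", "walkers", "adsorption_curve")


def _header(kind: str, params: dict, seed) -> str:
    items = ", ".join(f"{k}={v!r}" for k, v in sorted(params.items()))
    return f"# adsorbsim fixture kind={kind} seed={seed}\n# params: {items}\n"


def make_fixture(kind: str, params: dict, seed, path=None) -> str:
    """Generate a synthetic dataset as CSV text (optionally written to path).

    Kinds
    -----
    exponential_trace:
        Poisson-noised saturating exponential amp*(1-exp(-k*t)) on
        ``n_points`` times up to ``t_end``; ground truth (amp, k) in the
        header.  Params: amp, k, n_points (default 200), t_end (default
        5/k).
    walkers:
        Uniform initial walker positions in [0, L].  Params: n, L.
    adsorption_curve:
        Noise-free Langmuir–Schaefer curve.  Params: A, c_b, D, n_points
        (default 100), t_end.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    buf = io.StringIO()
    buf.write(_header(kind, params, seed))

    if kind == "exponential_trace":
        amp, k = params["amp"], params["k"]
        n_points = params.get("n_points", 200)
        t_end = params.get("t_end", 5.0 / k)
        t = np.linspace(0.0, t_end, n_points)
        mean = amp * -np.expm1(-k * t)
        y = rng.poisson(mean)
        buf.write("t,y\n")
        for ti, yi in zip(t, y):
            buf.write(f"{ti:.10g},{yi}\n")
    elif kind == "walkers":
        n, L = params["n"], params["L"]
        x = rng.uniform(0.0, L, size=n)
        buf.write("x\n")
        for xi in x:
            buf.write(f"{xi:.17g}\n")
    else:  # adsorption_curve
        A, c_b, D = params["A"], params["c_b"], params["D"]
        n_points = params.get("n_points", 100)
        t_end = params["t_end"]
        t = np.linspace(0.0, t_end, n_points)
        g = np.asarray(kinetics.gamma_langmuir_schaefer(t, A, c_b, D))
        buf.write("t,gamma\n")
        for ti, gi in zip(t, g):
            buf.write(f"{ti:.10g},{gi:.10g}\n")

    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
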