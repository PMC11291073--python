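"""Deterministic synthetic fixtures for tests and demonstrations.

Everything here is generated by the package itself at run time; the files
are small, plain-text, and byte-identical for a given seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .amplifier import AmplifierSettings, CellProperties
from .experiments import compute_iv
from .io import iv_to_csv, trace_to_csv
from .ionic import GenericINa, GenericINaParams, ModelCell
from .protocols import Protocol, build_iv_protocol, build_step_protocol
from .simulate import SolverOptions, simulate, simulate_ideal

__all__ = ["generate_fixtures", "fitting_dataset"]

#: The model-cell validation settings: machine estimates match the cell.
MODEL_CELL_SETTINGS = AmplifierSettings(
    alpha_R=0.0, alpha_P=0.0, Rs_est=30.0, Cm_est=22.0, Cp_est=4.0
)
MODEL_CELL = CellProperties(Rs=30.0, Cm=22.0, Cp=4.0)


def fitting_dataset(
    seed: int = 0,
    noise_sd: float = 0.0,
    test_voltages: tuple[float, ...] = (-30.0, -10.0, 10.0),
    dt_out: float = 0.05,
):
    """Synthetic 80%-compensated sweeps with known ground truth.

    The machine estimates of Rs and Cm are mis-set by ±5% relative to the
    truth, as in a realistic experiment.  Optional additive Gaussian
    observation noise (nA) is seeded.  Returns
    ``(truth, settings, protocols, traces, model_params)``.
    """
    truth = {
        "conductance": 0.45,  # μS
        "Rs": 8.0,  # MΩ
        "Cm": 18.0,  # pF
        "Voff": 2.0,  # mV
        "gleak": 0.001,  # μS (1 GΩ seal)
    }
    settings = AmplifierSettings(
        alpha_R=0.8,
        alpha_P=0.8,
        Rs_est=truth["Rs"] * 1.05,
        Cm_est=truth["Cm"] * 0.95,
        gleak_est=truth["gleak"] * 1.05,
    )
    model_params = GenericINaParams()
    cell = CellProperties(
        Rs=truth["Rs"], Cm=truth["Cm"], gleak=truth["gleak"], Voff=truth["Voff"]
    )
    model = GenericINa(model_params.with_conductance(truth["conductance"]))
    protocols = [Protocol(((-100.0, 5.0), (v, 10.0))) for v in test_voltages]
    opts = SolverOptions(rtol=1e-8, atol=1e-10, dt_out=dt_out)
    traces = [simulate(settings, cell, model, p, options=opts) for p in protocols]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for tr in traces:
            tr.Ipost = tr.Ipost + rng.normal(0.0, noise_sd, size=len(tr.t))
    return truth, settings, protocols, traces, model_params


def generate_fixtures(seed: int, outdir) -> list[Path]:
    """Write the small deterministic fixture files used by the test suite.

    Produces a model-cell trace at zero compensation, an ideal-clamp
    generic-INa I-V curve, and a three-sweep synthetic fitting dataset
    with its ground truth.  Identical seeds give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    header = [f"seed={seed}", "generator=vclamp.fixtures"]

    prot = build_step_protocol(-80.0, 20.0, 50.0, 20.0, 20.0)
    trace = simulate(
        MODEL_CELL_SETTINGS, MODEL_CELL, ModelCell(), prot,
        options=SolverOptions(dt_out=0.05),
    )
    p = outdir / "model_cell_trace.csv"
    trace_to_csv(trace, p, comments=header)
    written.append(p)

    protocols = build_iv_protocol(-100.0, 20.0, -80.0, 60.0, 10.0, 20.0)
    model = GenericINa()
    traces = [simulate_ideal(model, pr, dt_out=0.02) for pr in protocols]
    curve = compute_iv(traces, protocols)
    p = outdir / "generic_ina_ideal_iv.csv"
    iv_to_csv(curve, p, comments=header)
    written.append(p)

    truth, settings, prots, sweeps, _ = fitting_dataset(seed=seed)
    for i, (tr, pr) in enumerate(zip(sweeps, prots)):
        p = outdir / f"fit_sweep_{i}.csv"
        trace_to_csv(
            tr, p,
            comments=header + [f"step_mV={pr.segments[1][0]}"],
        )
        written.append(p)
    p = outdir / "fit_truth.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "truth": truth,
                "settings": {
                    "alpha_R": settings.alpha_R,
                    "alpha_P": settings.alpha_P,
                    "Rs_est": settings.Rs_est,
                    "Cm_est": settings.Cm_est,
                    "gleak_est": settings.gleak_est,
                },
                "seed": seed,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    written.append(p)
    return written
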