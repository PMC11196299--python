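"""Shared fixtures: synthetic cohorts and brute-force oracles."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from piezosleep import (
    PlmConfig,
    SimulationConfig,
    compute_envelopes,
    detect_cvhr,
    detect_events,
    detect_heartbeats,
    extract_components,
    log_amplitude,
    match_events,
    run_detection,
    simulate_cohort,
    simulate_subject,
)

#: Master seed for every seeded fixture in the suite.
SUITE_SEED = 1


def oracle_percentile(values: np.ndarray, percentile: float) -> float:
    """Independent nearest-rank percentile: full sort, ceil(p*m)-th value."""
    ordered = np.sort(np.asarray(values, dtype=float))
    k = max(1, math.ceil(percentile * len(ordered)))
    return float(ordered[k - 1])


def oracle_envelope_point(
    logamp: np.ndarray,
    mask: np.ndarray,
    rate: float,
    t: float,
    window_s: float,
    percentile: float,
) -> float | None:
    """Brute-force windowed percentile at one grid time (None if empty)."""
    n = len(logamp)
    c = int(round(t * rate))
    half = int(round(window_s * rate / 2.0))
    i0, i1 = max(0, c - half), min(n, c + half + 1)
    window = logamp[i0:i1][~mask[i0:i1]]
    if window.size == 0:
        return None
    return oracle_percentile(window, percentile)


@pytest.fixture(scope="session")
def clean_cohort():
    """20-subject cohort at clean settings (60% event depth, 5% noise),
    reference AHI spread evenly over 0-60/h, with detection products."""
    cohort = simulate_cohort(
        n=20,
        ahi_distribution={"kind": "linspace", "low": 0.0, "high": 60.0},
        base_config=SimulationConfig(duration_s=10800.0),
        seed=SUITE_SEED,
    )
    out = {
        "records": [],
        "truths": [],
        "metas": [],
        "envelopes": [],
        "events": [],
        "rei": [],
        "fcv": [],
        "ahi": [],
    }
    for record, truth, meta in cohort:
        comps = extract_components(record)
        env = compute_envelopes(
            log_amplitude(comps.respiration), comps.movement_mask, record.sampling_rate
        )
        events = detect_events(env)
        series = detect_heartbeats(comps.bcg, record.sampling_rate, comps.movement_mask)
        fcv = detect_cvhr(series, record.trt_hours).fcv
        out["records"].append(record)
        out["truths"].append(truth)
        out["metas"].append(meta)
        out["envelopes"].append(env)
        out["events"].append(events)
        out["rei"].append(len(events) / record.trt_hours)
        out["fcv"].append(fcv)
        out["ahi"].append(meta.ahi_trt)
    return out


@pytest.fixture(scope="session")
def plm_subject():
    """Six-hour recording with PLM-like trains and zero apneas.

    Posture shifts are disabled to isolate the PLM effect on REI and Fcv.
    """
    cfg = replace(
        SimulationConfig(duration_s=21600.0, event_rate_per_h=0.0, seed=11,
                         posture_shift_every_s=0.0),
        plm=PlmConfig(enabled=True),
    )
    record, truth = simulate_subject(cfg)
    rei_result = run_detection(record)
    comps = extract_components(record)
    series = detect_heartbeats(comps.bcg, record.sampling_rate, comps.movement_mask)
    cvhr = detect_cvhr(series, record.trt_hours)
    return {"record": record, "truth": truth, "rei": rei_result.rei, "fcv": cvhr.fcv}


@pytest.fixture(scope="session")
def small_subject():
    """One-hour, 20 events/h subject reused by several detector tests."""
    cfg = SimulationConfig(duration_s=3600.0, event_rate_per_h=20.0, seed=7)
    record, truth = simulate_subject(cfg)
    return record, truth
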