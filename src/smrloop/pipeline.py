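"""End-to-end analysis: from sessions to study endpoints and statistics.

For each subject and evaluation the three study endpoints are:

* ``ersp``: block-average ERSP (percent) at the individual alpha
  frequency over the task window — the sensorimotor desynchronization
  depth,
* ``n20``: z-scored N20 amplitude from the CPc-Fz montage — primary
  somatosensory cortex reactivity,
* ``sat_b``: saturation speed b (1/s) of the exponential speed-accuracy
  trade-off — the behavioral endpoint.

Each endpoint then enters a 2 (group) x 2 (evaluation) mixed
repeated-measures ANOVA whose interaction term carries the
training-effect question.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import behavior as bh
from . import sep as sep_mod
from . import spectral, stats
from .realtime import large_laplacian
from .recordings import EEGRecording, SEPRecording
from .synth import SubjectRecord, SubjectSession

logger = logging.getLogger(__name__)

TASK_WINDOW = (7.0, 12.0)   # trial seconds fully inside the task period

ENDPOINTS = ("ersp", "n20", "sat_b")


def eeg_endpoint(recording: EEGRecording) -> float:
    """Task-window ERSP at the estimated IAF (percent)."""
    lap = large_laplacian(recording)
    psd = spectral.welch_psd(lap, recording.sampling_rate, segment_s=2.0)
    try:
        params = spectral.parameterize_spectrum(psd)
        iaf = spectral.find_iaf(params)
    except (spectral.NoAlphaPeakError, ValueError):
        logger.info("no alpha peak found; falling back to 10 Hz")
        iaf = 10.0
    ersp_map = spectral.ersp_timefreq_map(recording)
    return spectral.block_average_ersp(
        ersp_map, window=TASK_WINDOW, foi=round(iaf)
    )


def sep_endpoint(recording: SEPRecording) -> float:
    """z-scored N20 amplitude (negative for deeper deflections)."""
    comps = sep_mod.extract_all(recording)
    for c in comps:
        if c.name == "N20":
            return c.amplitude_z
    raise ValueError("N20 montage missing from the SEP recording")


def behavior_endpoint(table: pd.DataFrame) -> float:
    """Saturation speed b from pooled per-condition success rates."""
    rates = bh.success_rates(table)
    fit = bh.fit_sat_curve(rates.index.to_numpy(), rates.to_numpy())
    return bh.saturation_speed(fit)


def session_endpoints(session: SubjectSession) -> dict[str, float]:
    eeg, sep_rec, table = session.generate()
    return {
        "ersp": eeg_endpoint(eeg),
        "n20": sep_endpoint(sep_rec),
        "sat_b": behavior_endpoint(table),
    }


def extract_endpoints(records: list[SubjectRecord]) -> pd.DataFrame:
    """Long endpoint table: subject, group, evaluation, endpoint, value."""
    rows = []
    for rec in records:
        for evaluation, session in sorted(rec.sessions.items()):
            values = session_endpoints(session)
            for endpoint, value in values.items():
                rows.append(
                    (rec.subject, rec.group, evaluation, endpoint, value)
                )
    return pd.DataFrame(
        rows, columns=["subject", "group", "evaluation", "endpoint", "value"]
    )


def group_anova(endpoints: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mixed 2x2 ANOVA (group x evaluation) per endpoint."""
    out = {}
    for endpoint, sub in endpoints.groupby("endpoint"):
        out[endpoint] = stats.mixed_anova_2x2(
            sub.rename(columns={"evaluation": "within"}),
        )
    return out
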