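"""Readers and writers for the pipeline's plain-text formats.

Trials travel as BIDS-like ``events.tsv`` (tab-separated, onset/duration in
seconds, dot decimal separator regardless of locale), covariates and ROI
time series as CSV, results as JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .task import CHOICE, NO_CHOICE, SubjectRecord, TaskConfig, TrialRecord

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "condition",
    "action",
    "outcome",
    "missed",
]

ROI_COLUMNS = ["time_s", "vis", "vs", "mpfc"]


class ParseError(ValueError):
    """Malformed row in a tabular input, with its line number."""


def trials_to_events(trials: list[TrialRecord], config: TaskConfig) -> pd.DataFrame:
    """Expand trial records into cue / response / outcome event rows."""
    rows = []
    for t in trials:
        cond = t.condition
        rows.append(
            dict(
                onset=t.cue_onset,
                duration=config.cue_duration,
                trial_type="cue_choice" if cond == CHOICE else "cue_nochoice",
                condition=cond,
                action=t.action or "n/a",
                outcome="n/a" if t.outcome is None else int(t.outcome),
                missed=int(t.missed),
            )
        )
        if t.missed:
            continue
        rows.append(
            dict(
                onset=t.response_onset,
                duration=0.0,
                trial_type="response",
                condition=cond,
                action=t.action,
                outcome=int(t.outcome),
                missed=0,
            )
        )
        rows.append(
            dict(
                onset=t.outcome_onset,
                duration=config.outcome_duration,
                trial_type="outcome_win" if t.outcome == 1 else "outcome_nowin",
                condition=cond,
                action=t.action,
                outcome=int(t.outcome),
                missed=0,
            )
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def events_to_trials(events: pd.DataFrame) -> list[TrialRecord]:
    """Reassemble trial records from an events table."""
    cues = events[events["trial_type"].str.startswith("cue")].sort_values("onset")
    trials = []
    for i, (_, cue) in enumerate(cues.iterrows()):
        cond = cue["condition"]
        missed = bool(int(cue["missed"]))
        later = events[(events["onset"] > cue["onset"])].sort_values("onset")
        resp = later[later["trial_type"] == "response"]
        outc = later[later["trial_type"].str.startswith("outcome")]
        if missed or len(resp) == 0 or len(outc) == 0:
            trials.append(
                TrialRecord(
                    index=i,
                    condition=cond,
                    cue_onset=float(cue["onset"]),
                    response_onset=float(cue["onset"]) + 1.0,
                    outcome_onset=float(cue["onset"]) + 2.0,
                    missed=True,
                )
            )
            continue
        r = resp.iloc[0]
        o = outc.iloc[0]
        action = cue["action"] if cue["action"] != "n/a" else None
        trials.append(
            TrialRecord(
                index=i,
                condition=cond,
                cue_onset=float(cue["onset"]),
                response_onset=float(r["onset"]),
                outcome_onset=float(o["onset"]),
                action=action,
                forced_action=action if cond == NO_CHOICE else None,
                outcome=int(o["outcome"]),
                missed=False,
            )
        )
    return trials


def write_events(path, trials: list[TrialRecord], config: TaskConfig) -> None:
    trials_to_events(trials, config).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path, config: TaskConfig | None = None) -> list[TrialRecord]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for lineno, onset in enumerate(df["onset"], start=2):
        try:
            float(onset)
        except (TypeError, ValueError):
            raise ParseError(f"{path}:{lineno}: non-numeric onset {onset!r}") from None
    if config is not None:
        beyond = df["onset"] > config.session_length
        if beyond.any():
            warnings.warn(
                f"{int(beyond.sum())} events fall after the end of the session", UserWarning
            )
    return events_to_trials(df)


def write_covariates(path, covariates: pd.DataFrame) -> None:
    covariates.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "qids", "hads_a", "age", "sex", "site", "mde"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_roi_timeseries(path, data: np.ndarray, tr: float) -> None:
    """ROI series as CSV with header time_s, vis, vs, mpfc."""
    data = np.asarray(data, dtype=float)
    t = np.arange(data.shape[0]) * tr
    pd.DataFrame(
        {"time_s": t, "vis": data[:, 0], "vs": data[:, 1], "mpfc": data[:, 2]}
    ).to_csv(path, index=False, float_format="%.8f")


def read_roi_timeseries(path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    tr = float(np.median(np.diff(t))) if t.size > 1 else float("nan")
    return df[["vis", "vs", "mpfc"]].to_numpy(dtype=float), tr


def write_inputs(path, inputs: np.ndarray, channels) -> None:
    """Input stimulus functions as channel-labelled TSV at microtime resolution."""
    pd.DataFrame(np.asarray(inputs, dtype=float), columns=list(channels)).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_inputs(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_results(path, results: dict) -> None:
    Path(path).write_text(json.dumps(_jsonify(results), indent=2, sort_keys=True) + "\n")


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())
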