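"""Sign-consistency diagnostic on fitted or external summary statistics.

The diagnostic examines, across variants whose interaction (and
optionally main-effect) p-values pass a priori thresholds, whether the
interaction estimates bear a fixed sign relationship to their main
genetic effects.  A monotone convex outcome transformation and a
threshold-based endogenous treatment each force such a relationship
(aligned or opposed, depending on curvature and the exposure effect's
sign), so a rate near 1 flags that the observed interactions may be
artifacts of scaling or exposure endogeneity — while a mixed pattern
rules those mechanisms out as the sole driver.

The rate is defined as the proportion of selected interactions showing
the *more prevalent* relationship, hence lies in [0.5, 1] whenever any
variants are selected.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .regress import FitTable

__all__ = [
    "SignConsistencyReport",
    "sign_consistency_rate",
    "read_summary_stats",
    "write_report",
    "report_from_json",
    "validate_report_dict",
    "CAVEAT",
]

SCHEMA_VERSION = 1

#: Interpretive caveat included in every rendered report.
CAVEAT = (
    "No universal sign-consistency level identifies outcome scaling or "
    "treatment endogeneity as the driver of observed interactions; a high "
    "rate warrants closer scrutiny of the measurement scale and exposure "
    "assignment, not an automatic conclusion."
)

REQUIRED_SUMMARY_COLUMNS = ["id", "beta_main", "p_main", "gamma_int", "p_int"]

# minimal structural schema (field name -> allowed types); None encodes JSON null
_SCHEMA = {
    "schema_version": (int,),
    "n_tested": (int,),
    "n_selected": (int,),
    "n_aligned": (int,),
    "n_opposed": (int,),
    "n_zero_excluded": (int,),
    "rate": (float, int, type(None)),
    "majority_relationship": (str, type(None)),
    "binomial_p": (float, int, type(None)),
    "p_int_threshold": (float, int),
    "p_main_threshold": (float, int),
    "notes": (dict,),
}


@dataclass
class SignConsistencyReport:
    n_tested: int
    n_selected: int
    n_aligned: int
    n_opposed: int
    n_zero_excluded: int
    rate: float | None
    majority_relationship: str | None
    binomial_p: float | None
    p_int_threshold: float
    p_main_threshold: float
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        d.setdefault("notes", {})
        d["notes"] = dict(d["notes"])
        d["notes"].setdefault("caveat", CAVEAT)
        return d

    def to_markdown(self) -> str:
        lines = [
            "# Sign-consistency report",
            "",
            f"- variants tested: {self.n_tested}",
            f"- selected (p_int < {self.p_int_threshold:g}, "
            f"p_main < {self.p_main_threshold:g}): {self.n_selected}",
            f"- aligned (sgn gamma = sgn beta): {self.n_aligned}",
            f"- opposed (sgn gamma = -sgn beta): {self.n_opposed}",
            f"- exact zero estimates excluded: {self.n_zero_excluded}",
        ]
        if self.rate is None:
            lines.append("- rate: NA (no variants passed the filters)")
        else:
            lines.append(
                f"- rate: {self.rate:.4f} (majority {self.majority_relationship}; "
                f"two-sided binomial p vs 1/2: {self.binomial_p:.3g})"
            )
        for k, v in self.notes.items():
            lines.append(f"- note[{k}]: {v}")
        lines += ["", f"> {CAVEAT}", ""]
        return "\n".join(lines)


def sign_consistency_rate(
    fits: FitTable,
    p_int_threshold: float = 0.05,
    p_main_threshold: float = 1.0,
    notes: dict | None = None,
) -> SignConsistencyReport:
    """Sign-consistency rate among interactions passing the a priori filters.

    Selection: ``p_int < p_int_threshold`` and ``p_main < p_main_threshold``
    (set the latter to 1.0 to disable the nominal main-effect filter).
    Variants with an exactly zero beta or gamma estimate are excluded from
    both counts and reported separately.  The binomial p-value against a
    null rate of 1/2 is a labelled aid, not part of the rate's definition.
    """
    for name, thr in (("p_int_threshold", p_int_threshold),
                      ("p_main_threshold", p_main_threshold)):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    t = fits.table
    sel = t[(t["p_int"] < p_int_threshold) & (t["p_main"] < p_main_threshold)]
    zero = (sel["beta_main"] == 0) | (sel["gamma_int"] == 0)
    n_zero = int(zero.sum())
    sel = sel[~zero]
    n_sel = len(sel)
    aligned = (sel["gamma_int"] > 0) == (sel["beta_main"] > 0)
    n_aligned = int(aligned.sum())
    n_opposed = n_sel - n_aligned
    report_notes = dict(notes or {})
    if n_sel == 0:
        report_notes.setdefault("empty_selection", "no variants passed the filters")
        rate = majority = binom_p = None
    else:
        rate = max(n_aligned, n_opposed) / n_sel
        majority = "aligned" if n_aligned >= n_opposed else "opposed"
        binom_p = float(stats.binomtest(n_aligned, n_sel, 0.5).pvalue)
    return SignConsistencyReport(
        n_tested=len(t), n_selected=n_sel, n_aligned=n_aligned, n_opposed=n_opposed,
        n_zero_excluded=n_zero, rate=rate, majority_relationship=majority,
        binomial_p=binom_p, p_int_threshold=float(p_int_threshold),
        p_main_threshold=float(p_main_threshold), notes=report_notes,
    )


def read_summary_stats(path) -> FitTable:
    """Read a per-variant summary-statistics TSV into a :class:`FitTable`.

    The header must contain ``id, beta_main, p_main, gamma_int, p_int``
    (extra columns, e.g. standard errors, are carried through).  Rows with
    missing or non-numeric required fields are rejected with their line
    numbers; duplicate ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in REQUIRED_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics file {path} missing column(s): {missing}")
    bad_lines = []
    for col in REQUIRED_SUMMARY_COLUMNS[1:]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            bad_lines.extend((int(i) + 2, col) for i in df.index[bad])
        df[col] = numeric
    if df["id"].isna().any():
        bad_lines.extend((int(i) + 2, "id") for i in df.index[df["id"].isna()])
    if bad_lines:
        desc = ", ".join(f"line {ln} ({col})" for ln, col in sorted(bad_lines))
        raise ValueError(f"missing/non-numeric required fields in {path}: {desc}")
    return FitTable(df)


def write_report(report: SignConsistencyReport, json_path, markdown_path=None) -> None:
    """Serialize a report as JSON (machine) and optionally Markdown (human).

    Numbers are serialized at full precision; an NA rate becomes JSON null
    with an explanatory note.
    """
    d = report.to_dict()
    validate_report_dict(d)
    Path(json_path).write_text(json.dumps(d, indent=2) + "\n")
    if markdown_path is not None:
        Path(markdown_path).write_text(report.to_markdown())


def report_from_json(json_path) -> SignConsistencyReport:
    d = json.loads(Path(json_path).read_text())
    validate_report_dict(d)
    d.pop("schema_version", None)
    return SignConsistencyReport(**d)


def validate_report_dict(d: dict) -> None:
    """Structural validation of a serialized report against the shipped schema."""
    if not isinstance(d, dict):
        raise ValueError("report must be a JSON object")
    for key, types in _SCHEMA.items():
        if key not in d:
            raise ValueError(f"report missing field {key!r}")
        v = d[key]
        if isinstance(v, bool) or not isinstance(v, types):
            raise ValueError(f"report field {key!r} has invalid type {type(v).__name__}")
    if d["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {d['schema_version']}")
    if d["rate"] is not None and not 0.5 <= d["rate"] <= 1.0 and not math.isnan(d["rate"]):
        raise ValueError("rate must lie in [0.5, 1] when defined")
    extras = set(d) - set(_SCHEMA)
    if extras:
        raise ValueError(f"unknown report fields: {sorted(extras)}")
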