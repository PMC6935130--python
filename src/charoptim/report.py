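"""Serialising fit reports to TSV and JSON.

TSV output rounds displayed ratios to 4 decimals; JSON keeps full double
precision and round-trips through :func:`report_from_json`.
"""

from __future__ import annotations

import json
from fractions import Fraction

from .indices import CharacterFit, FitReport

_ENSEMBLE_COLUMNS = ["Topology", "TreeLength", "CI", "HI", "RI", "AC"]
_CHAR_COLUMNS = ["Topology", "Char", "Ordered", "Weight", "m", "s", "g", "ci", "ri"]
_CHANGE_COLUMNS = [
    "Topology", "Mode", "Char", "Branch", "From", "To", "Steps",
    "Internal", "Ambiguous", "UniqueUnreversed",
]


def _r4(x) -> str:
    return "n/a" if x is None else f"{float(x):.4f}"


def write_report(report, fmt: str = "tsv", provenance: dict | None = None) -> str:
    """Serialise one FitReport or a list of them.

    TSV: an ensemble row per topology, then a per-character appendix
    (m, s, g, ci, ri) and the classified change lists, in deterministic
    column order.  JSON: full precision, suitable for round-tripping.
    """
    reports = [report] if isinstance(report, FitReport) else list(report)
    if fmt == "json":
        doc = {
            "provenance": provenance or {},
            "reports": [r.to_dict() for r in reports],
        }
        return json.dumps(doc, indent=2, sort_keys=True)
    if fmt != "tsv":
        raise ValueError(f"unknown report format {fmt!r}")

    lines = []
    for key, val in (provenance or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append("\t".join(_ENSEMBLE_COLUMNS))
    for r in reports:
        lines.append(
            "\t".join(
                [r.topology, str(r.tree_length), _r4(r.CI), _r4(r.HI),
                 _r4(r.RI), str(r.AC)]
            )
        )
    lines.append("")
    lines.append("\t".join(_CHAR_COLUMNS))
    for r in reports:
        for f in r.character_fits:
            lines.append(
                "\t".join(
                    [
                        r.topology, str(f.index + 1),
                        "yes" if f.ordered else "no", str(f.weight),
                        str(f.m), str(f.s), str(f.g), _r4(f.ci), _r4(f.ri),
                    ]
                )
            )
    lines.append("")
    lines.append("\t".join(_CHANGE_COLUMNS))
    for r in reports:
        for mode in ("acctran", "deltran"):
            for c in r.changes(mode):
                lines.append(
                    "\t".join(
                        [
                            r.topology, mode, str(c.char_index + 1),
                            f"{c.parent_label} -> {c.child_label}",
                            str(c.from_state), str(c.to_state), str(c.steps),
                            "yes" if c.on_internal_branch else "no",
                            "yes" if c.ambiguous else "no",
                            "yes" if c.unique_unreversed else "no",
                        ]
                    )
                )
    return "\n".join(lines) + "\n"


def report_from_json(text: str) -> list:
    """Rebuild reports from :func:`write_report`'s JSON output.

    Change lists are restored as plain dictionaries (tree node objects are
    not serialisable); ensemble values and per-character fits are exact
    round-trips up to double precision.
    """
    doc = json.loads(text)
    out = []
    for d in doc["reports"]:
        fits = [
            CharacterFit(
                index=c["char"] - 1,
                m=c["m"], s=c["s"], g=c["g"],
                weight=c["weight"], ordered=c["ordered"],
            )
            for c in d["characters"]
        ]
        rep = FitReport(
            topology=d["topology"],
            tree_length=d["tree_length"],
            CI=None if d["CI"] is None else Fraction(d["CI"]).limit_denominator(10 ** 9),
            RI=None if d["RI"] is None else Fraction(d["RI"]).limit_denominator(10 ** 9),
            AC=d["AC"],
            character_fits=fits,
        )
        rep.raw_changes = {
            "acctran": d.get("acctran_changes", []),
            "deltran": d.get("deltran_changes", []),
        }
        out.append(rep)
    return out
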