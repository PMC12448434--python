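"""Result serialization and the run manifest.

All numeric output is written at full floating precision (``repr`` of the
float), so an export/import round trip is bit-exact and two runs with the same
parameters and seed produce byte-identical files.
"""

from __future__ import annotations

import csv
import datetime
import json
import os
from dataclasses import dataclass, field

__all__ = ["RunManifest", "export_results", "write_rows", "read_rows"]


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one model run: the seed is recorded for every stochastic stage."""

    seed: int
    n_microsim: int = 0
    n_psa: int = 0
    discount_rate_used: float = 0.03
    perspectives: tuple[str, ...] = ("GOVERNMENT", "SOCIETAL")
    timestamp: str = field(default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds"))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "n_microsim": self.n_microsim,
                    "n_psa": self.n_psa,
                    "discount_rate_used": self.discount_rate_used,
                    "perspectives": list(self.perspectives),
                    "timestamp": self.timestamp,
                },
                fh,
                indent=2,
            )


def write_rows(rows: list[tuple[str, float]], path: str, header: tuple[str, str] = ("parameter", "value")) -> None:
    """Write labelled values as delimited text; empty rows give a header-only file."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for label, value in rows:
            writer.writerow([label, repr(float(value))])


def read_rows(path: str) -> list[tuple[str, float]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        return [(label, float(value)) for label, value in reader]


def export_results(results, outdir: str) -> dict[str, str]:
    """Serialize a :class:`~mnhcea.model.CEAResults` to CSV tables + JSON.

    Writes a Table-3-style summary, the full cost ledger, the outcome impacts
    and a JSON bundle mirroring every numeric output.  Returns the paths.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    paths["summary"] = os.path.join(outdir, "summary.csv")
    write_rows(results.summary_rows(), paths["summary"])

    paths["ledger"] = os.path.join(outdir, "ledger.csv")
    with open(paths["ledger"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "payer", "direction", "amount"])
        for line in results.ledger:
            writer.writerow([line.label, line.payer, line.direction, repr(line.amount)])

    paths["outcomes"] = os.path.join(outdir, "outcomes.csv")
    with open(paths["outcomes"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["condition", "cases_averted", "severity", "severity_cases"])
        for impact in results.impacts.values():
            if impact.severity_split:
                for sev, cases in impact.severity_split.items():
                    writer.writerow([impact.condition, repr(impact.cases_averted), sev, repr(cases)])
            else:
                writer.writerow([impact.condition, repr(impact.cases_averted), "", ""])

    paths["deaths"] = os.path.join(outdir, "deaths_averted.csv")
    write_rows([(d.cause, d.count) for d in results.deaths], paths["deaths"], header=("cause", "count"))

    paths["json"] = os.path.join(outdir, "results.json")
    bundle = {
        "summary": {label: value for label, value in results.summary_rows()},
        "icers": results.icers.as_dict(),
        "effects": results.effects,
        "deaths_averted": {d.cause: d.count for d in results.deaths},
        "dalys": {
            "lys_undiscounted": results.daly_model.lys_undiscounted,
            "dalys_discounted_model": results.daly_model.dalys_discounted,
            "dalys_reported": results.dalys_reported,
            "discount_rate": results.daly_model.discount_rate,
        },
        "meta": results.meta,
    }
    with open(paths["json"], "w") as fh:
        json.dump(bundle, fh, indent=2)
    return paths
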