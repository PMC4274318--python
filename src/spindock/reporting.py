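"""XPLOR-style energy breakdown and restraint-violation reports.

The text layouts mirror the classic minimiser printouts — a pipe-delimited
Etotal block and a per-restraint table with R<average>, target, bounds,
signed Delta and energy, closed by the NOEPRI RMS/violation line — so that
runs are directly comparable, by eye, with published protocols.  All
numbers print to three decimals; reports are byte-stable for identical
inputs and round-trip through JSON.

The bonded terms (BOND/ANGL/DIHE/IMPR) always print 0.000: no bonded
force field acts here, whereas a full-force-field run would inherit those
terms from its starting coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .docking import EnergyBreakdown, ProtocolResult
from .restraints import RestraintParams, RestraintRow, noe_summary

__all__ = ["RunReport", "format_energy_block", "format_noe_rows"]

_RULE = "-" * 84


def format_energy_block(e: EnergyBreakdown) -> str:
    """Pipe-delimited energy breakdown block (three decimals)."""
    t = e.terms
    lines = [
        _RULE,
        f"| Etotal ={e.etotal:.3f} grad(E)={e.grad_norm:.3f} "
        f"E(BOND)={t['BOND']:.3f} E(ANGL)={t['ANGL']:.3f} |",
        f"| E(DIHE)={t['DIHE']:.3f} E(IMPR)={t['IMPR']:.3f} "
        f"E(VDW)={t['VDW']:.3f} E(ELEC)={t['ELEC']:.3f} |",
        f"| E(NCS)={t['NCS']:.3f} E(NOE)={t['NOE']:.3f} |",
        _RULE,
    ]
    return "\n".join(lines)


def format_noe_rows(rows, params: RestraintParams, class_name: str = "EPR") -> str:
    """Per-restraint violation table with the NOEPRI summary line."""
    lines = [
        f"++++++++++++ CLASS {class_name} ++++++++++++++",
        f"for this class: SCALe={params.scale:.3f} AVERage={params.averaging} "
        f"POTEntial=square-well",
    ]
    rows = list(rows)
    for r in rows:
        lines.append(
            f"R<average> = {r.r_average:.3f} NOE = {r.d_target:.2f} "
            f"(-{r.d_minus:.2f}/+{r.d_plus:.2f}) Delta = {r.delta:.3f} "
            f"E(NOE) = {r.energy:.3f}"
        )
    if rows:
        s = noe_summary(rows)
        lines.append(
            f"NOEPRI: RMS diff. = {s.rms:.3f}, #(violat.> 0.0)= "
            f"{s.n_violated} of {s.n_total} NOEs"
        )
    else:
        lines.append("NOEPRI: RMS diff. = 0.000, #(violat.> 0.0)= 0 of 0 NOEs")
    return "\n".join(lines)


@dataclass
class RunReport:
    """Serialisable record of a staged docking run."""

    stages: list  # [(name, pre EnergyBreakdown, post EnergyBreakdown)]
    params: RestraintParams
    outputs: dict = field(default_factory=dict)

    @classmethod
    def from_protocol(cls, result: ProtocolResult,
                      params: RestraintParams) -> "RunReport":
        return cls(
            stages=[(s.name, s.pre, s.post) for s in result.stages],
            params=params,
            outputs=dict(result.outputs),
        )

    @property
    def final_breakdown(self) -> EnergyBreakdown:
        return self.stages[-1][2]

    def to_text(self) -> str:
        chunks = []
        for name, pre, post in self.stages:
            chunks.append(f"Stage {name}: before minimisation")
            chunks.append(format_energy_block(pre))
            chunks.append(f"Stage {name}: after minimisation")
            chunks.append(format_energy_block(post))
        last = self.final_breakdown
        chunks.append("NOE energy breakdown:")
        chunks.append(format_noe_rows(last.noe_rows, self.params))
        return "\n".join(chunks) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": [
                    {"name": n, "pre": pre.to_dict(), "post": post.to_dict()}
                    for n, pre, post in self.stages
                ],
                "params": vars(self.params).copy(),
                "outputs": dict(self.outputs),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        data = json.loads(text)

        def mk(d):
            return EnergyBreakdown(
                etotal=d["etotal"],
                grad_norm=d["grad_norm"],
                terms=d["terms"],
                noe_rows=[RestraintRow(**r) for r in d["noe_rows"]],
            )

        return cls(
            stages=[(s["name"], mk(s["pre"]), mk(s["post"]))
                    for s in data["stages"]],
            params=RestraintParams(**data["params"]),
            outputs=data.get("outputs", {}),
        )
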