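"""Growth-condition sets: named maps of exchange-reaction bounds.

A :class:`ConditionSet` captures one medium / environment as explicit
(lower, upper) flux bounds on exchange reactions, e.g. carbon-monoxide
uptake open and hydrogen export closed.  Applying a condition set
overwrites the listed bounds on a copy of the model and touches nothing
else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

from .errors import ValidationError


@dataclass
class ConditionSet:
    """Named exchange-bound map defining a growth condition."""

    id: str = "default"
    description: str = ""
    exchange_bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for rxn_id, (lo, hi) in self.exchange_bounds.items():
            if lo > hi:
                raise ValidationError(
                    f"condition {self.id!r}: bounds for {rxn_id!r} inverted "
                    f"({lo} > {hi})"
                )

    def to_dict(self) -> dict:
        return {
            "description": self.description,
            "exchange_bounds": {
                rid: [float(lo), float(hi)]
                for rid, (lo, hi) in sorted(self.exchange_bounds.items())
            },
        }

    @classmethod
    def from_dict(cls, id: str, data: dict) -> "ConditionSet":
        bounds = {
            str(rid): (float(pair[0]), float(pair[1]))
            for rid, pair in (data.get("exchange_bounds") or {}).items()
        }
        cond = cls(
            id=id, description=str(data.get("description", "")), exchange_bounds=bounds
        )
        cond.validate()
        return cond
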