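"""Run reports: lossless JSON records of what a command computed and how."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

from .inference import RcpEstimate, TestResult

TOOL_VERSION = "0.1.0"


def _encode_result(obj: RcpEstimate | TestResult) -> dict[str, Any]:
    d = dataclasses.asdict(obj)
    d["kind"] = "estimate" if isinstance(obj, RcpEstimate) else "test"
    return d


def _decode_result(d: dict[str, Any]) -> RcpEstimate | TestResult:
    d = dict(d)
    kind = d.pop("kind")
    cls = RcpEstimate if kind == "estimate" else TestResult
    return cls(**d)


@dataclass
class RunReport:
    """Everything needed to reproduce one CLI run: inputs, parameters, seed."""

    command: str
    inputs: list[str] = field(default_factory=list)
    parameters: dict[str, Any] = field(default_factory=dict)
    results: list[RcpEstimate | TestResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    tool_version: str = TOOL_VERSION
    seed: int | None = None

    def to_json(self, indent: int | None = 2) -> str:
        d = {
            "command": self.command,
            "inputs": self.inputs,
            "parameters": self.parameters,
            "results": [_encode_result(r) for r in self.results],
            "warnings": self.warnings,
            "tool_version": self.tool_version,
            "seed": self.seed,
        }
        return json.dumps(d, indent=indent, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        d["results"] = [_decode_result(r) for r in d["results"]]
        return cls(**d)
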