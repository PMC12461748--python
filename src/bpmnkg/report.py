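"""Structured findings shared by the table linter and the graph validator.

A report is an ordered list of findings; it *passes* exactly when no finding
has error severity.  Findings serialize to JSON lines so they can be consumed
by scripts as well as read by humans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"
    INFO = "info"


@dataclass(frozen=True)
class Finding:
    severity: Severity
    code: str
    subject: str
    message: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "severity": self.severity.value,
                "code": self.code,
                "element_id": self.subject,
                "message": self.message,
            },
            ensure_ascii=False,
        )

    def __str__(self) -> str:  # human-readable single line
        return f"[{self.severity.value.upper():7s}] {self.code}: {self.subject}: {self.message}"


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(f.severity is Severity.ERROR for f in self.findings)

    def add(self, severity: Severity, code: str, subject: str, message: str) -> None:
        self.findings.append(Finding(severity, code, subject, message))

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity is Severity.ERROR]

    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity is Severity.WARNING]

    def by_code(self, code: str) -> list[Finding]:
        return [f for f in self.findings if f.code == code]

    def extend(self, other: "ValidationReport") -> None:
        self.findings.extend(other.findings)

    def to_json_lines(self) -> str:
        return "\n".join(f.to_json() for f in self.findings)

    def __str__(self) -> str:
        if not self.findings:
            return "no findings"
        return "\n".join(str(f) for f in self.findings)
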