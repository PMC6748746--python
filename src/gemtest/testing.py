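"""Project test discovery, execution and reporting.

Test cases are plain Python functions in ``tests/test_*.py`` files inside
a project directory.  Each function takes ``(model, project)`` and makes
ordinary ``assert`` statements about the freshly materialized model.  The
:func:`model_test_selector` decorator parametrizes a test over the
cartesian product of model ids × condition ids × design ids; an
undecorated test runs once against the default model.

For every expanded instance the runner builds a fresh model — load,
apply the condition set, then apply the design (a design's embedded
conditions are applied last and therefore override project conditions on
conflicting reactions) — so records are independent of execution order.

Outcomes: ``pass``, ``fail`` (an assertion failed) or ``error``
(any other exception, including unloadable test files).
"""

from __future__ import annotations

import fnmatch
import importlib.util
import json as _json
import random
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Union

from .delta import apply_design
from .errors import GemtestError
from .optimize import apply_conditions
from .project import (
    ProjectConfig,
    design_resolver,
    list_conditions,
    list_designs,
    load_model,
    load_project_design,
)

PASS = "pass"
FAIL = "fail"
ERROR = "error"

_SELECTOR_ATTR = "_gemtest_selector"
_WILDCARD = "*"


@dataclass
class TestSelector:
    """Parametrization of one test over models × conditions × designs.

    Empty lists mean the documented defaults: the project default model,
    unconstrained conditions, the wild type.  The wildcard ``"*"`` in
    ``design_ids`` expands to every registered design.
    """

    model_ids: List[str] = field(default_factory=list)
    condition_ids: List[str] = field(default_factory=list)
    design_ids: List[str] = field(default_factory=list)


def _as_list(value: Union[None, str, Sequence[str]]) -> List[str]:
    if value is None:
        return []
    if isinstance(value, str):
        return [value]
    return list(value)


def model_test_selector(
    model_ids: Union[None, str, Sequence[str]] = None,
    condition_ids: Union[None, str, Sequence[str]] = None,
    design_ids: Union[None, str, Sequence[str]] = None,
) -> Callable:
    """Decorator attaching a :class:`TestSelector` to a test function."""
    selector = TestSelector(
        model_ids=_as_list(model_ids),
        condition_ids=_as_list(condition_ids),
        design_ids=_as_list(design_ids),
    )

    def decorate(func):
        setattr(func, _SELECTOR_ATTR, selector)
        return func

    return decorate


@dataclass
class TestRecord:
    """Outcome of one executed test instance."""

    test_id: str
    outcome: str
    message: str = ""
    duration: float = 0.0


@dataclass
class TestReport:
    """Aggregated outcomes of one project test run."""

    project_name: str
    timestamp: str
    records: List[TestRecord] = field(default_factory=list)

    @property
    def counts(self) -> dict:
        tally = {PASS: 0, FAIL: 0, ERROR: 0}
        for record in self.records:
            tally[record.outcome] += 1
        return tally

    @property
    def ok(self) -> bool:
        counts = self.counts
        return counts[FAIL] == 0 and counts[ERROR] == 0

    def to_dict(self) -> dict:
        return {
            "project": self.project_name,
            "timestamp": self.timestamp,
            "counts": self.counts,
            "records": [
                {
                    "test_id": r.test_id,
                    "outcome": r.outcome,
                    "message": r.message,
                    "duration": r.duration,
                }
                for r in self.records
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TestReport":
        return cls(
            project_name=data["project"],
            timestamp=data["timestamp"],
            records=[
                TestRecord(
                    test_id=r["test_id"],
                    outcome=r["outcome"],
                    message=r.get("message", ""),
                    duration=float(r.get("duration", 0.0)),
                )
                for r in data["records"]
            ],
        )


@dataclass
class TestCase:
    """One discovered test function (or an unloadable file placeholder)."""

    file: str
    name: str
    func: Optional[Callable] = None
    selector: TestSelector = field(default_factory=TestSelector)
    load_error: Optional[str] = None


def discover_tests(project: ProjectConfig) -> List[TestCase]:
    """Collect test functions from ``test_*.py`` files in the project's
    tests directory.

    A file that fails to import yields a single placeholder case whose
    execution records an error outcome instead of crashing the run.
    """
    cases: List[TestCase] = []
    tests_dir = project.tests_path
    if not tests_dir.is_dir():
        raise GemtestError(f"tests directory missing: {tests_dir}")
    for path in sorted(tests_dir.glob("test_*.py")):
        module_name = f"gemtest_project_tests_{path.stem}"
        spec = importlib.util.spec_from_file_location(module_name, path)
        module = importlib.util.module_from_spec(spec)
        try:
            spec.loader.exec_module(module)
        except Exception as exc:
            cases.append(
                TestCase(
                    file=path.name,
                    name="<load>",
                    load_error=f"{type(exc).__name__}: {exc}",
                )
            )
            continue
        for name, obj in vars(module).items():
            if name.startswith("test_") and callable(obj):
                selector = getattr(obj, _SELECTOR_ATTR, TestSelector())
                cases.append(
                    TestCase(file=path.name, name=name, func=obj, selector=selector)
                )
    return cases


def _expand(project: ProjectConfig, case: TestCase):
    models = case.selector.model_ids or [None]
    conditions = case.selector.condition_ids or [None]
    designs: List[Optional[str]] = []
    for did in case.selector.design_ids or [None]:
        if did == _WILDCARD:
            designs.extend(list_designs(project))
        else:
            designs.append(did)
    if not designs:
        designs = [None]
    for model_id in models:
        for condition_id in conditions:
            for design_id in designs:
                label = "/".join(
                    part if part is not None else "-"
                    for part in (model_id or "default", condition_id, design_id)
                )
                yield (
                    f"{case.file}::{case.name}[{label}]",
                    model_id,
                    condition_id,
                    design_id,
                )


def _materialize(project, model_id, condition_id, design_id):
    model = load_model(project, model_id)
    if condition_id is not None:
        conditions = list_conditions(project)
        if condition_id not in conditions:
            raise GemtestError(f"unknown condition set {condition_id!r}")
        model = apply_conditions(model, conditions[condition_id])
    if design_id is not None:
        design = load_project_design(project, design_id)
        model = apply_design(model, design, design_resolver(project))
    return model


def run_tests(
    project: ProjectConfig,
    filter: Optional[str] = None,
    order_seed: Optional[int] = None,
) -> TestReport:
    """Execute every (discovered × expanded) test instance and aggregate a
    report.

    ``filter`` keeps only test ids containing the pattern (glob syntax
    also accepted).  ``order_seed`` shuffles execution order; because
    every instance gets a freshly materialized model, outcomes are
    independent of order.
    """
    report = TestReport(
        project_name=project.name,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    instances = []
    for case in discover_tests(project):
        if case.load_error is not None:
            record = TestRecord(
                test_id=f"{case.file}::{case.name}",
                outcome=ERROR,
                message=case.load_error,
            )
            if _matches(record.test_id, filter):
                report.records.append(record)
            continue
        for test_id, model_id, condition_id, design_id in _expand(project, case):
            if _matches(test_id, filter):
                instances.append((test_id, case, model_id, condition_id, design_id))
    if order_seed is not None:
        random.Random(order_seed).shuffle(instances)
    for test_id, case, model_id, condition_id, design_id in instances:
        start = time.perf_counter()
        try:
            model = _materialize(project, model_id, condition_id, design_id)
            case.func(model, project)
        except AssertionError as exc:
            outcome, message = FAIL, str(exc) or "assertion failed"
        except Exception as exc:
            outcome, message = ERROR, f"{type(exc).__name__}: {exc}"
        else:
            outcome, message = PASS, ""
        report.records.append(
            TestRecord(
                test_id=test_id,
                outcome=outcome,
                message=message,
                duration=time.perf_counter() - start,
            )
        )
    return report


def _matches(test_id: str, pattern: Optional[str]) -> bool:
    if pattern is None:
        return True
    return pattern in test_id or fnmatch.fnmatch(test_id, pattern)


def format_report_text(report: TestReport) -> str:
    """Human-readable summary."""
    lines = [f"project: {report.project_name}", f"run at:  {report.timestamp}", ""]
    for record in report.records:
        lines.append(f"[{record.outcome.upper():5s}] {record.test_id}")
        if record.message:
            lines.append(f"        {record.message}")
    counts = report.counts
    lines.append("")
    lines.append(
        f"{len(report.records)} tests: {counts[PASS]} passed, "
        f"{counts[FAIL]} failed, {counts[ERROR]} errors"
    )
    return "\n".join(lines) + "\n"


def write_report(report: TestReport, path, format: str = "json") -> None:
    """Write a report as machine-readable JSON or the text summary."""
    path = Path(path)
    if format == "json":
        path.write_text(
            _json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    elif format == "text":
        path.write_text(format_report_text(report))
    else:
        raise GemtestError(f"unsupported report format {format!r}")


def report_exit_status(report: TestReport) -> int:
    """0 iff the run contains no failures and no errors."""
    return 0 if report.ok else 1
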