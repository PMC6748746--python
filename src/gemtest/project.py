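"""Project directory layout, configuration registry and scaffolding.

A project is one directory of flat, diffable files tying together
models, growth conditions, strain designs and test cases::

    my_project/
        project.yml         configuration registry (this module)
        <model>.json        models in the canonical JSON dialect
        conditions.yml      named condition sets (exchange-bound maps)
        designs/            *.json delta documents, *.py programmatic designs
        tests/test_*.py     test cases run by gemtest.testing

Everything is plain text so the whole project can live under version
control; creation is byte-stable given the same inputs, and all registry
reads are read-only on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import io_formats
from .conditions import ConditionSet
from .delta import StrainDesign, load_design, load_programmatic_design, save_design
from .errors import ProjectError
from .model import Model
from .templates import SCAFFOLD_TESTS

CONFIG_FILENAME = "project.yml"
CONDITIONS_FILENAME = "conditions.yml"
DESIGNS_DIRNAME = "designs"
TESTS_DIRNAME = "tests"
CONFIG_VERSION = "1.0"


@dataclass
class ProjectConfig:
    """Registry of one project directory.

    Paths are stored relative to ``root`` so the directory can be moved
    or cloned freely.
    """

    root: Path
    name: str
    default_model: str
    models: List[str] = field(default_factory=list)
    conditions_file: str = CONDITIONS_FILENAME
    designs_dir: str = DESIGNS_DIRNAME
    tests_dir: str = TESTS_DIRNAME
    config_version: str = CONFIG_VERSION

    @property
    def config_path(self) -> Path:
        return self.root / CONFIG_FILENAME

    @property
    def conditions_path(self) -> Path:
        return self.root / self.conditions_file

    @property
    def designs_path(self) -> Path:
        return self.root / self.designs_dir

    @property
    def tests_path(self) -> Path:
        return self.root / self.tests_dir

    def to_dict(self) -> dict:
        return {
            "config_version": self.config_version,
            "name": self.name,
            "default_model": self.default_model,
            "models": sorted(self.models),
            "conditions_file": self.conditions_file,
            "designs_dir": self.designs_dir,
            "tests_dir": self.tests_dir,
        }

    def validate(self) -> None:
        if self.default_model not in self.models:
            raise ProjectError(
                f"default model {self.default_model!r} is not in the model "
                f"registry {sorted(self.models)}"
            )
        for rel in [self.conditions_file, *self.models]:
            if not (self.root / rel).exists():
                raise ProjectError(f"project file missing on disk: {self.root / rel}")
        for rel in (self.designs_dir, self.tests_dir):
            if not (self.root / rel).is_dir():
                raise ProjectError(
                    f"project directory missing on disk: {self.root / rel}"
                )


def _write_config(config: ProjectConfig) -> None:
    text = yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    config.config_path.write_text(text)


def create_project(
    root_path,
    initial_model: Model,
    name: Optional[str] = None,
    force: bool = False,
) -> ProjectConfig:
    """Scaffold a new project directory around ``initial_model``.

    Writes the config, the model (canonical JSON dialect), an empty
    conditions file, an empty designs directory and a tests directory
    containing the default scaffold tests (model loads, model grows,
    every design applies and stays feasible).  Refuses a non-empty root
    unless ``force`` is set.  The resulting tree is byte-stable given the
    same inputs.
    """
    root = Path(root_path)
    if root.exists() and any(root.iterdir()) and not force:
        raise ProjectError(
            f"directory {root} is not empty; pass force=True to scaffold anyway"
        )
    initial_model.validate()
    root.mkdir(parents=True, exist_ok=True)
    (root / DESIGNS_DIRNAME).mkdir(exist_ok=True)
    (root / TESTS_DIRNAME).mkdir(exist_ok=True)
    model_file = f"{initial_model.id}.json"
    io_formats.write_json_model(initial_model, root / model_file)
    (root / CONDITIONS_FILENAME).write_text("{}\n")
    (root / TESTS_DIRNAME / "test_model.py").write_text(SCAFFOLD_TESTS)
    config = ProjectConfig(
        root=root,
        name=name or initial_model.id,
        default_model=model_file,
        models=[model_file],
    )
    _write_config(config)
    config.validate()
    return config


def load_project(root_path) -> ProjectConfig:
    """Load and validate the configuration of an existing project."""
    root = Path(root_path)
    config_path = root / CONFIG_FILENAME
    if not config_path.exists():
        raise ProjectError(f"no {CONFIG_FILENAME} in {root}")
    try:
        data = yaml.safe_load(config_path.read_text())
    except yaml.YAMLError as exc:
        raise ProjectError(f"cannot parse {config_path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ProjectError(f"{config_path} does not contain a mapping")
    missing = {"name", "default_model", "models"} - set(data)
    if missing:
        raise ProjectError(f"{config_path} is missing keys {sorted(missing)}")
    config = ProjectConfig(
        root=root,
        name=str(data["name"]),
        default_model=str(data["default_model"]),
        models=[str(m) for m in data["models"]],
        conditions_file=str(data.get("conditions_file", CONDITIONS_FILENAME)),
        designs_dir=str(data.get("designs_dir", DESIGNS_DIRNAME)),
        tests_dir=str(data.get("tests_dir", TESTS_DIRNAME)),
        config_version=str(data.get("config_version", CONFIG_VERSION)),
    )
    config.validate()
    return config


def _model_file_for(project: ProjectConfig, model_id: Optional[str]) -> str:
    if model_id is None:
        return project.default_model
    for rel in project.models:
        if rel == model_id or Path(rel).stem == model_id:
            return rel
    raise ProjectError(
        f"no model {model_id!r} in project {project.name!r}; registered: "
        f"{sorted(project.models)}"
    )


def load_model(project: ProjectConfig, model_id: Optional[str] = None) -> Model:
    """Load a registered model (the default when ``model_id`` is None)."""
    rel = _model_file_for(project, model_id)
    path = project.root / rel
    if not path.exists():
        raise ProjectError(f"registered model file missing: {path}")
    return io_formats.read_model(path)


def add_model(
    project: ProjectConfig, model: Model, set_default: bool = False
) -> str:
    """Store a model in the project (canonical JSON) and register it."""
    model_file = f"{model.id}.json"
    io_formats.write_json_model(model, project.root / model_file)
    if model_file not in project.models:
        project.models.append(model_file)
    if set_default:
        project.default_model = model_file
    _write_config(project)
    return model_file


def list_conditions(project: ProjectConfig) -> Dict[str, ConditionSet]:
    """All condition sets from the project conditions file."""
    data = yaml.safe_load(project.conditions_path.read_text()) or {}
    if not isinstance(data, dict):
        raise ProjectError(f"{project.conditions_path} does not contain a mapping")
    return {
        str(cid): ConditionSet.from_dict(str(cid), cdata or {})
        for cid, cdata in data.items()
    }


def save_conditions(project: ProjectConfig, conditions: Dict[str, ConditionSet]):
    """Rewrite the conditions file (sorted, flat YAML)."""
    payload = {cid: cond.to_dict() for cid, cond in sorted(conditions.items())}
    text = yaml.safe_dump(payload, sort_keys=True, default_flow_style=False)
    if not payload:
        text = "{}\n"
    project.conditions_path.write_text(text)


def list_designs(project: ProjectConfig) -> List[str]:
    """Ids of all registered designs: ``*.json`` delta documents and
    ``*.py`` programmatic designs in the designs directory."""
    ids = set()
    for path in project.designs_path.glob("*.json"):
        ids.add(path.stem)
    for path in project.designs_path.glob("*.py"):
        if not path.stem.startswith("_"):
            ids.add(path.stem)
    return sorted(ids)


def load_project_design(project: ProjectConfig, design_id: str) -> StrainDesign:
    """Load one design by id, dispatching on stored vs programmatic form."""
    json_path = project.designs_path / f"{design_id}.json"
    if json_path.exists():
        return load_design(json_path)
    py_path = project.designs_path / f"{design_id}.py"
    if py_path.exists():
        return load_programmatic_design(project, design_id)
    raise ProjectError(
        f"no design {design_id!r} in project {project.name!r}; registered: "
        f"{list_designs(project)}"
    )


def add_design(project: ProjectConfig, design: StrainDesign) -> Path:
    """Store a design as a JSON delta document in the designs directory."""
    path = project.designs_path / f"{design.id}.json"
    save_design(design, path)
    return path


def design_resolver(project: ProjectConfig):
    """A parent-design resolver backed by the project's designs directory
    (for :func:`gemtest.apply_design`)."""

    def resolve(design_id: str) -> StrainDesign:
        return load_project_design(project, design_id)

    return resolve
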