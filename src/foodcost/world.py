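"""The ``World`` bundle: every input table the pipeline consumes, with
plain-text (CSV/JSON) round-tripping and a reproducibility manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cra import RelativeRiskModel, validate_burden
from .errors import DataError
from .lcia import validate_catalog
from .monetize import MonetarizationFactors
from .scenarios import validate_classes, validate_densities, validate_eat_targets
from .supply import normalize_weights, validate_registry, validate_supply

_TABLES = (
    "supply",
    "catalog",
    "weights",
    "registry",
    "classes",
    "densities",
    "eat_targets",
    "burden",
)

_RR_COLS = [
    "risk_factor", "disease", "rr_per_unit", "rr_lower", "rr_upper",
    "serving_size", "tmrel", "direction",
]


@dataclass
class World:
    """A complete, self-consistent input bundle for the pipeline.

    ``truth`` (optional) carries the synthetic generator's own analytic
    accounting of the world it built — per-item per-kcal intensities and
    baseline impacts — used by tests as a known-truth oracle.  It is not an
    input to any pipeline stage.
    """

    supply: pd.DataFrame
    catalog: pd.DataFrame
    weights: pd.DataFrame
    registry: pd.DataFrame
    classes: pd.DataFrame
    densities: pd.DataFrame
    eat_targets: pd.DataFrame
    burden: pd.DataFrame
    rr_models: list[RelativeRiskModel]
    mf: MonetarizationFactors = field(default_factory=MonetarizationFactors)
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def validate(self) -> "World":
        """Run every consuming module's type invariants over the bundle."""
        validate_supply(self.supply)
        validate_catalog(self.catalog)
        normalize_weights(self.weights)
        validate_registry(self.registry)
        validate_classes(self.classes)
        validate_densities(self.densities, set(self.supply["fbs_group"]))
        validate_eat_targets(self.eat_targets)
        validate_burden(self.burden)
        # countries enter only with both supply and expenditure present
        reg = self.registry.set_index("country")
        missing = set(self.supply["country"]) - set(reg.index)
        if missing:
            raise DataError(f"supply countries missing from registry: {sorted(missing)}")
        no_fce = reg.index[reg["fce_pc"] <= 0]
        if len(no_fce):
            raise DataError(f"countries without expenditure data: {sorted(no_fce)}")
        return self

    # -- persistence --------------------------------------------------------

    def to_dir(self, path: str | Path) -> Path:
        """Write the bundle as a directory of CSV/JSON files + manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in _TABLES:
            getattr(self, name).to_csv(path / f"{name}.csv", index=False)
        rr = pd.DataFrame(
            [[getattr(m, c) for c in _RR_COLS] for m in self.rr_models], columns=_RR_COLS
        )
        rr.to_csv(path / "rr_models.csv", index=False)
        mf_fields = {
            f.name: getattr(self.mf, f.name)
            for f in dataclasses.fields(self.mf)
            if f.init
        }
        (path / "monetarization.json").write_text(json.dumps(mf_fields, indent=2))
        for name, df in self.truth.items():
            df.to_csv(path / f"truth_{name}.csv", index=False)
        (path / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "World":
        path = Path(path)
        tables = {name: pd.read_csv(path / f"{name}.csv") for name in _TABLES}
        rr = pd.read_csv(path / "rr_models.csv")
        models = [RelativeRiskModel(**row) for row in rr.to_dict("records")]
        mf = MonetarizationFactors(**json.loads((path / "monetarization.json").read_text()))
        truth = {
            p.stem.removeprefix("truth_"): pd.read_csv(p)
            for p in sorted(path.glob("truth_*.csv"))
        }
        manifest = {}
        if (path / "manifest.json").exists():
            manifest = json.loads((path / "manifest.json").read_text())
        return cls(rr_models=models, mf=mf, truth=truth, manifest=manifest, **tables)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for run manifests."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
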