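"""Pipeline configuration: one plain-text (INI) file drives every stage."""

from __future__ import annotations

import configparser
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .behavior import BehaviorModelParams
from .design import DesignSpec


@dataclass
class PipelineConfig:
    """All stage parameters of the end-to-end analysis.

    Either ``input_path`` (an existing trial-log CSV) or ``simulate`` plus
    a task must be given. Validation happens before any stage runs.
    """

    # input
    input_path: str | None = None
    simulate: bool = False
    task: str = "spatial_stroop"
    n_participants: int = 5
    design_seed: int = 1
    response_seed: int = 2
    model: BehaviorModelParams = field(default_factory=BehaviorModelParams)
    # exclusions
    rpt_lo: int = -200
    rpt_hi: int = 1000
    drop_late: bool = False
    # tachometric stage
    span: float = 0.2
    degree: int = 2
    pool_bin_width: int = 1
    # permutation stage
    permutation_B: int = 1000
    permutation_seed: int = 3
    sidedness: str = "one_sided"
    # bootstrap stage
    bootstrap_reps: int = 1000
    bootstrap_seed: int = 4
    # binned stage
    bin_width: int = 100
    bin_lo: int = 0
    bin_hi: int = 1000
    # output
    out_dir: str = "tachometry_out"
    make_figures: bool = True

    def validate(self) -> None:
        if not self.simulate and self.input_path is None:
            raise ValueError("config needs either input_path or simulate = true")
        if self.simulate and self.input_path is not None:
            raise ValueError("give input_path or simulate, not both")
        if not 0 < self.span <= 1:
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.rpt_lo >= self.rpt_hi:
            raise ValueError("rpt window must be increasing")
        if self.permutation_B < 1 or self.bootstrap_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.sidedness not in ("one_sided", "two_sided"):
            raise ValueError(f"bad sidedness {self.sidedness!r}")
        if self.bin_width < 1 or self.bin_lo >= self.bin_hi:
            raise ValueError("bad binning parameters")
        self.model.validate()

    def design_spec(self) -> DesignSpec:
        return DesignSpec(
            task=self.task,
            n_participants=self.n_participants,
            seed=self.design_seed,
        )

    # -- plain-text round trip ------------------------------------------------

    _SECTIONS = {
        "input": ("input_path", "simulate", "task", "n_participants",
                  "design_seed", "response_seed"),
        "exclusions": ("rpt_lo", "rpt_hi", "drop_late"),
        "tachometric": ("span", "degree", "pool_bin_width"),
        "permutation": ("permutation_B", "permutation_seed", "sidedness"),
        "bootstrap": ("bootstrap_reps", "bootstrap_seed"),
        "binned": ("bin_width", "bin_lo", "bin_hi"),
        "output": ("out_dir", "make_figures"),
    }

    def to_ini(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {}
            for k in keys:
                v = getattr(self, k)
                if v is not None:
                    cp[section][k] = str(v)
        cp["model"] = {
            k: str(v) for k, v in asdict(self.model).items() if k != "rt_bounds"
        }
        cp["model"]["rt_lo"] = str(self.model.rt_bounds[0])
        cp["model"]["rt_hi"] = str(self.model.rt_bounds[1])
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        kwargs = {}
        for section, keys in cls._SECTIONS.items():
            if section not in cp:
                continue
            for k in keys:
                if k not in cp[section]:
                    continue
                raw = cp[section][k]
                default = getattr(cls, k, None)
                f = cls.__dataclass_fields__[k]
                typ = f.type
                if typ.startswith("bool") or k in ("simulate", "drop_late",
                                                   "make_figures"):
                    kwargs[k] = raw.strip().lower() == "true"
                elif k in ("span",):
                    kwargs[k] = float(raw)
                elif k in ("input_path", "task", "sidedness", "out_dir"):
                    kwargs[k] = raw
                else:
                    kwargs[k] = int(raw)
        cfg = cls(**kwargs)
        if "model" in cp:
            mp = cp["model"]
            model_kwargs = {
                k: float(mp[k]) for k in mp
                if k in BehaviorModelParams.__dataclass_fields__
            }
            model = BehaviorModelParams(**model_kwargs)
            if "rt_lo" in mp and "rt_hi" in mp:
                model.rt_bounds = (float(mp["rt_lo"]), float(mp["rt_hi"]))
            cfg.model = model
        return cfg
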