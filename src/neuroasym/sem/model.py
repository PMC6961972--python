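"""Declarative specification of latent-variable models.

A model is a list of parameters over three matrices of the structural
equation system  v = A v + u,  u ~ N(M, S), where v stacks observed then
latent variables:

* ``path``  — a directed edge A[target, source]: a loading (latent ->
  observed) or a structural regression;
* ``var`` / ``cov`` — entries of the symmetric residual matrix S;
* ``mean`` — intercepts/means M (latent means default to 0).

Each parameter is free (with an optional start value) or fixed.  Free
parameters sharing a label are a single underlying parameter, which is how
equality constraints — within or across groups — are expressed.  In a
multigroup model a parameter with ``group=None`` applies identically to all
groups, while ``group='<label>'`` applies to that group only.

Identification follows the standardized-latent convention: every latent
variable without an explicit variance entry gets its (residual) variance
fixed at 1 and all loadings free; latent means are fixed at 0 unless
declared.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["Parameter", "ModelSpec"]

_KINDS = ("path", "cov", "var", "mean")


@dataclass
class Parameter:
    kind: str                 # path | cov | var | mean
    target: str
    source: str | None = None  # None for var/mean (implied = target)
    free: bool = True
    value: float | None = None  # start value if free (None = data-derived), fixed value otherwise
    label: str | None = None
    group: str | None = None   # None = applies to (and is shared across) all groups

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind in ("var", "mean"):
            self.source = self.target if self.kind == "var" else None
        if not self.free and self.value is None:
            raise ValueError(f"fixed parameter {self.key()} needs an explicit value")

    def key(self) -> tuple:
        if self.kind == "cov":
            a, b = sorted((self.target, self.source))
            return (self.kind, a, b, self.group)
        return (self.kind, self.target, self.source, self.group)

    def default_label(self) -> str:
        base = {
            "path": f"{self.target}~{self.source}",
            "cov": f"{self.target}~~{self.source}",
            "var": f"{self.target}~~{self.target}",
            "mean": f"{self.target}~1",
        }[self.kind]
        return base if self.group is None else f"{base}@{self.group}"


@dataclass
class ModelSpec:
    """Observed/latent variable lists plus the parameter table."""

    observed: list[str]
    latent: list[str] = field(default_factory=list)
    params: list[Parameter] = field(default_factory=list)
    group_var: str | None = None
    name: str = "model"

    # -- builder interface -------------------------------------------------
    def _add(self, p: Parameter) -> "ModelSpec":
        known = set(self.observed) | set(self.latent)
        for v in (p.target, p.source):
            if v is not None and v not in known:
                raise ValueError(f"parameter references unknown variable {v!r}")
        existing = {q.key() for q in self.params}
        if p.key() in existing:
            raise ValueError(f"duplicate parameter {p.key()}")
        self.params.append(p)
        return self

    def add_loading(self, factor: str, indicator: str, *, free: bool = True,
                    value: float | None = None, label: str | None = None,
                    group: str | None = None) -> "ModelSpec":
        return self._add(Parameter("path", indicator, factor, free, value, label, group))

    def add_regression(self, target: str, source: str, *, free: bool = True,
                       value: float | None = None, label: str | None = None,
                       group: str | None = None) -> "ModelSpec":
        return self._add(Parameter("path", target, source, free, value, label, group))

    def add_covariance(self, a: str, b: str, *, free: bool = True,
                       value: float | None = None, label: str | None = None,
                       group: str | None = None) -> "ModelSpec":
        return self._add(Parameter("cov", a, b, free, value, label, group))

    def add_variance(self, v: str, *, free: bool = True, value: float | None = None,
                     label: str | None = None, group: str | None = None) -> "ModelSpec":
        return self._add(Parameter("var", v, None, free, value, label, group))

    def add_mean(self, v: str, *, free: bool = True, value: float | None = None,
                 label: str | None = None, group: str | None = None) -> "ModelSpec":
        return self._add(Parameter("mean", v, None, free, value, label, group))

    # -- utilities ---------------------------------------------------------
    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)

    def find(self, kind: str, target: str, source: str | None = None,
             group: str | None = None) -> Parameter:
        probe = Parameter(kind, target, source, free=True, group=group)
        for p in self.params:
            if p.key() == probe.key():
                return p
        raise KeyError(f"no parameter {probe.key()} in model {self.name!r}")

    def fix_parameter(self, kind: str, target: str, source: str | None = None,
                      value: float = 0.0, group: str | None = None) -> "ModelSpec":
        """Return a copy with the named parameter fixed at ``value``."""
        out = self.copy()
        p = out.find(kind, target, source, group)
        p.free = False
        p.value = value
        p.label = None
        return out

    def equate(self, keys: list[tuple], label: str) -> "ModelSpec":
        """Return a copy in which the named free parameters share one label."""
        if len(keys) < 2:
            raise ValueError("an equality constraint needs at least two parameters")
        out = self.copy()
        for kind, target, source in keys:
            p = out.find(kind, target, source)
            if not p.free:
                raise ValueError(f"cannot equate fixed parameter {p.key()}")
            p.label = label
        return out

    def complete(self, structural_targets_have_disturbance: bool = True) -> "ModelSpec":
        """Fill in conventional defaults for anything not declared explicitly.

        Observed variables get a free residual variance and a free mean;
        latent variables get a variance fixed at 1 (the standardized-latent
        identification convention) — for endogenous latents this is the
        disturbance variance.
        """
        out = self.copy()
        have = {p.key() for p in out.params}
        for v in out.observed:
            if ("var", v, v, None) not in have:
                out.add_variance(v)
            if ("mean", v, None, None) not in have:
                out.add_mean(v)
        for v in out.latent:
            if ("var", v, v, None) not in have:
                out.add_variance(v, free=False, value=1.0)
        return out

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "observed": list(self.observed),
            "latent": list(self.latent),
            "group_var": self.group_var,
            "params": [asdict(p) for p in self.params],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        spec = cls(observed=list(d["observed"]), latent=list(d.get("latent", [])),
                   group_var=d.get("group_var"), name=d.get("name", "model"))
        for pd_ in d.get("params", []):
            spec._add(Parameter(**pd_))
        return spec

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ModelSpec":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        return cls.from_dict(yaml.safe_load(text))
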