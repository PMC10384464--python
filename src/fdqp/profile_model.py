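"""Versioned data-quality profiles (DQPs) and their XML serialization.

A data-quality profile is the document exchanged between a federation
server and its edge nodes in place of raw patient data.  It bundles

* the attribute schema ``A`` with per-attribute importance weights ``W``
  (weights sum to 1 and double as feature-selection priorities),
* the set of profiled quality dimensions ``D`` (completeness, accuracy,
  timeliness, uniqueness, validity, consistency),
* minimum acceptable tolerance levels ``T`` per dimension,
* the repair rules ``R`` (condition -> imputation/deletion action), and
* optionally the measured per-attribute statistics ``M``.

Profiles are versioned: the baseline profile starts at version 0, each
federation round increments the version, and after the first round only
:class:`ProfileDelta` patches are exchanged.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from lxml import etree

__all__ = [
    "QualityDimension",
    "DataType",
    "ProfileRole",
    "RuleAction",
    "RuleCondition",
    "QualityRule",
    "AttributeSpec",
    "AttributeMeasures",
    "WorkloadStub",
    "DQProfile",
    "ProfileDelta",
    "ProfileError",
    "initialize_profile",
    "validate_profile",
    "normalize_weights",
    "write_profile_xml",
    "read_profile_xml",
    "diff_profiles",
    "apply_delta",
    "profiles_equal",
]

#: Weight sums are accepted when within this of 1.0.
WEIGHT_SUM_TOL = 1e-9
#: Numeric agreement required of measures invariants (completeness vs missing).
MEASURE_IDENTITY_TOL = 1e-12


class ProfileError(ValueError):
    """Raised when a profile, delta or XML document is structurally invalid."""


class QualityDimension(str, Enum):
    COMPLETENESS = "completeness"
    ACCURACY = "accuracy"
    TIMELINESS = "timeliness"
    UNIQUENESS = "uniqueness"
    VALIDITY = "validity"
    CONSISTENCY = "consistency"


class DataType(str, Enum):
    NUMERIC = "numeric"
    CATEGORICAL = "categorical"
    DATETIME = "datetime"


class ProfileRole(str, Enum):
    BASELINE = "baseline"
    EDGE = "edge"
    FEDERATED = "federated"


class RuleAction(str, Enum):
    """Concrete repair actions a quality rule may prescribe.

    The enum *values* are the spellings used in the XML dialect.
    """

    NONE = "None"
    MEAN_IMPUTE = "ImputeMean"
    MEDIAN_IMPUTE = "ImputeMedian"
    MODE_IMPUTE = "ImputeMode"
    KNN_IMPUTE = "ImputeKNN"
    MULTIPLE_IMPUTE = "ImputeMultiple"
    DROP_COLUMN = "DeleteColumn"
    DROP_ROWS = "DeleteRows"


@dataclass(frozen=True)
class RuleCondition:
    """Predicate over per-attribute state deciding whether a rule fires.

    The missing-fraction interval is ``[missing_min, missing_max)`` except
    that an upper bound of exactly 1.0 is inclusive, so a column-deletion
    band such as [0.5, 1.0] covers fully missing columns.  ``None`` fields
    are wildcards.
    """

    missing_min: float = 0.0
    missing_max: float = 1.0
    data_type: DataType | None = None
    skew_class: str | None = None  # "skewed" | "symmetric"
    weight_min: float | None = None
    weight_max: float | None = None
    mnar: bool | None = None

    def well_formed(self) -> bool:
        if not (0.0 <= self.missing_min <= self.missing_max <= 1.0):
            return False
        if self.weight_min is not None and self.weight_max is not None:
            if self.weight_min > self.weight_max:
                return False
        if self.skew_class not in (None, "skewed", "symmetric"):
            return False
        return True

    def matches(
        self,
        missing_fraction: float,
        data_type: DataType,
        skew_class: str | None,
        weight: float,
        mnar: bool,
    ) -> bool:
        mf = missing_fraction
        in_band = self.missing_min <= mf < self.missing_max or (
            self.missing_max >= 1.0 and mf >= self.missing_min
        )
        if not in_band:
            return False
        if self.data_type is not None and self.data_type != data_type:
            return False
        if self.skew_class is not None and self.skew_class != skew_class:
            return False
        if self.weight_min is not None and weight < self.weight_min:
            return False
        if self.weight_max is not None and weight > self.weight_max:
            return False
        if self.mnar is not None and self.mnar != mnar:
            return False
        return True


@dataclass
class QualityRule:
    """One condition -> action pair, identified by a dotted id like ``"2.1"``."""

    rule_id: str
    dimension: QualityDimension
    condition: RuleCondition
    action: RuleAction
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class AttributeSpec:
    name: str
    data_type: DataType = DataType.NUMERIC
    allowed_min: float | None = None
    allowed_max: float | None = None
    weight: float | None = None
    tolerances: dict[QualityDimension, float] = field(default_factory=dict)
    rule_ids: list[str] = field(default_factory=list)


@dataclass
class AttributeMeasures:
    """Measured per-attribute statistics (the profile's ``M`` component).

    ``cv`` (coefficient of variation) backs the dataset-level consistency
    score; it is optional because it is undefined for categorical or
    zero-mean attributes.  A fully missing column is recorded with
    ``missing_fraction`` 1 and ``None``/NaN summary values.
    """

    observed_min: Any = None
    observed_max: Any = None
    mode: Any = None
    skewness: float = math.nan
    missing_fraction: float = 0.0
    unique_fraction: float = 0.0
    outlier_fraction: float = 0.0
    completeness: float = 1.0
    cv: float | None = None


@dataclass
class WorkloadStub:
    """Opaque edge workload descriptor; carried verbatim, never interpreted."""

    config: dict[str, Any] = field(default_factory=dict)
    realtime: dict[str, Any] = field(default_factory=dict)


@dataclass
class DQProfile:
    version: int = 0
    role: ProfileRole = ProfileRole.BASELINE
    node_id: str | None = None
    row_count: int = 0
    attributes: list[AttributeSpec] = field(default_factory=list)
    dimensions: set[QualityDimension] = field(default_factory=set)
    rules: list[QualityRule] = field(default_factory=list)
    measures: dict[str, AttributeMeasures] | None = None
    workload: WorkloadStub | None = None
    selected_features: list[str] | None = None

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    def attribute(self, name: str) -> AttributeSpec:
        for spec in self.attributes:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def rule(self, rule_id: str) -> QualityRule:
        for rule in self.rules:
            if rule.rule_id == rule_id:
                return rule
        raise KeyError(rule_id)

    def copy(self) -> "DQProfile":
        return copy.deepcopy(self)


@dataclass
class ProfileDelta:
    """Exact patch between two profile versions.

    ``changed_fields`` holds ``(path, old, new)`` triples over the profile's
    canonical flattened representation; the sentinel string ``"__absent__"``
    marks fields added or removed between versions.
    """

    version_from: int
    version_to: int
    changed_fields: list[tuple[str, Any, Any]] = field(default_factory=list)


_ABSENT = "__absent__"


# ---------------------------------------------------------------------------
# Construction & validation
# ---------------------------------------------------------------------------

def normalize_weights(weights: Sequence[float]) -> list[float]:
    """Rescale *weights* to sum to 1.  Idempotent; rejects non-positive sums."""
    total = float(sum(weights))
    if total <= 0:
        raise ProfileError("weights must have a positive sum")
    return [float(w) / total for w in weights]


def initialize_profile(
    attribute_specs: Sequence[AttributeSpec],
    dimensions: Iterable[QualityDimension],
    rules: Sequence[QualityRule] = (),
    *,
    normalize: bool = False,
) -> DQProfile:
    """Create the baseline profile (version 0, no measures).

    Omitted weights default to uniform 1/D.  Explicit weights must already
    sum to 1 unless ``normalize=True``.
    """
    specs = [copy.deepcopy(s) for s in attribute_specs]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ProfileError("duplicate attribute names")
    rule_ids = [r.rule_id for r in rules]
    if len(set(rule_ids)) != len(rule_ids):
        raise ProfileError("duplicate rule ids")
    given = [s.weight for s in specs]
    if all(w is None for w in given):
        for s in specs:
            s.weight = 1.0 / len(specs)
    else:
        if any(w is None for w in given):
            raise ProfileError("either all or no attribute weights may be given")
        for w in given:
            if not (0.0 <= w <= 1.0):  # type: ignore[operator]
                raise ProfileError(f"weight {w} outside [0, 1]")
        total = float(sum(given))  # type: ignore[arg-type]
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            if not normalize:
                raise ProfileError(
                    f"attribute weights sum to {total}, not 1 "
                    "(pass normalize=True to rescale)"
                )
            for s, w in zip(specs, normalize_weights(given)):  # type: ignore[arg-type]
                s.weight = w
    return DQProfile(
        version=0,
        role=ProfileRole.BASELINE,
        attributes=specs,
        dimensions=set(dimensions),
        rules=list(copy.deepcopy(list(rules))),
        measures=None,
    )


def validate_profile(profile: DQProfile) -> list[str]:
    """Return the list of invariant violations (empty iff the profile is valid)."""
    v: list[str] = []
    if profile.version < 0:
        v.append(f"version {profile.version} is negative")
    if profile.row_count < 0:
        v.append(f"row_count {profile.row_count} is negative")
    names = [s.name for s in profile.attributes]
    if len(set(names)) != len(names):
        v.append("duplicate attribute names")
    rule_ids = [r.rule_id for r in profile.rules]
    if len(set(rule_ids)) != len(rule_ids):
        v.append("duplicate rule ids")
    weights = [s.weight for s in profile.attributes]
    if any(w is None for w in weights):
        v.append("attribute weight missing")
    else:
        for s in profile.attributes:
            if not (0.0 <= s.weight <= 1.0):  # type: ignore[operator]
                v.append(f"attribute {s.name}: weight {s.weight} outside [0, 1]")
        if profile.attributes:
            total = float(sum(weights))  # type: ignore[arg-type]
            if abs(total - 1.0) > WEIGHT_SUM_TOL:
                v.append(f"attribute weight sum {total} != 1")
    for s in profile.attributes:
        for dim, tol in s.tolerances.items():
            if not (0.0 <= tol <= 1.0):
                v.append(
                    f"attribute {s.name}: tolerance {tol} for {dim.value} "
                    "outside [0, 1]"
                )
        if s.allowed_min is not None and s.allowed_max is not None:
            if s.allowed_min > s.allowed_max:
                v.append(f"attribute {s.name}: allowed_min > allowed_max")
    for rule in profile.rules:
        if not rule.condition.well_formed():
            v.append(f"rule {rule.rule_id}: malformed condition interval")
    if profile.measures is not None:
        missing = set(names) - set(profile.measures)
        if missing:
            v.append(f"measures absent for attributes: {sorted(missing)}")
        for name, m in profile.measures.items():
            for fname in ("missing_fraction", "unique_fraction",
                          "outlier_fraction", "completeness"):
                val = getattr(m, fname)
                if not (0.0 <= val <= 1.0):
                    v.append(f"measures[{name}].{fname} = {val} outside [0, 1]")
            if abs(m.completeness - (1.0 - m.missing_fraction)) > MEASURE_IDENTITY_TOL:
                v.append(
                    f"measures[{name}]: completeness != 1 - missing_fraction"
                )
            if (
                isinstance(m.observed_min, (int, float))
                and isinstance(m.observed_max, (int, float))
                and not (math.isnan(m.observed_min) or math.isnan(m.observed_max))
                and m.observed_min > m.observed_max
            ):
                v.append(f"measures[{name}]: observed_min > observed_max")
    return v


# ---------------------------------------------------------------------------
# XML serialization
# ---------------------------------------------------------------------------
# Dialect: Profile / Dimensions / Attributes / Attribute / Tolerances /
# RuleRefs / Measures / Rules / Rule / Condition / Param /
# FederatedFeatures / Workload.  Floats use Python repr (shortest exact
# round-trip form, >= 12 significant digits).

def _fmt(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _typed_el(parent: etree._Element, tag: str, value: Any) -> None:
    if value is None:
        return
    el = etree.SubElement(parent, tag)
    if isinstance(value, bool):
        el.set("type", "bool")
    elif isinstance(value, int):
        el.set("type", "int")
    elif isinstance(value, float):
        el.set("type", "float")
    else:
        el.set("type", "str")
    el.set("value", _fmt(value))


def _typed_read(el: etree._Element) -> Any:
    kind = el.get("type", "str")
    raw = el.get("value")
    if raw is None:
        raise ProfileError(f"element <{el.tag}> lacks a value attribute")
    if kind == "int":
        return int(raw)
    if kind == "float":
        return float(raw)
    if kind == "bool":
        return raw == "true"
    return raw


def write_profile_xml(profile: DQProfile, path: str | Path | None = None) -> bytes:
    """Serialize *profile* to UTF-8 XML; optionally also write it to *path*."""
    root = etree.Element("Profile")
    root.set("version", str(profile.version))
    root.set("role", profile.role.value)
    if profile.node_id is not None:
        root.set("nodeId", profile.node_id)
    root.set("rowCount", str(profile.row_count))

    dims = etree.SubElement(root, "Dimensions")
    for d in sorted(profile.dimensions, key=lambda d: d.value):
        etree.SubElement(dims, "Dimension").set("name", d.value)

    attrs = etree.SubElement(root, "Attributes")
    for spec in profile.attributes:
        a = etree.SubElement(attrs, "Attribute")
        a.set("id", spec.name)
        a.set("dataType", spec.data_type.value)
        if spec.weight is not None:
            a.set("weight", _fmt(float(spec.weight)))
        if spec.allowed_min is not None:
            a.set("allowedMin", _fmt(float(spec.allowed_min)))
        if spec.allowed_max is not None:
            a.set("allowedMax", _fmt(float(spec.allowed_max)))
        if spec.tolerances:
            tols = etree.SubElement(a, "Tolerances")
            for dim in sorted(spec.tolerances, key=lambda d: d.value):
                t = etree.SubElement(tols, "Tolerance")
                t.set("dimension", dim.value)
                t.set("value", _fmt(float(spec.tolerances[dim])))
        if spec.rule_ids:
            refs = etree.SubElement(a, "RuleRefs")
            for rid in spec.rule_ids:
                etree.SubElement(refs, "RuleRef").set("id", rid)
        if profile.measures is not None and spec.name in profile.measures:
            m = profile.measures[spec.name]
            me = etree.SubElement(a, "Measures")
            me.set("missing", _fmt(float(m.missing_fraction)))
            me.set("unique", _fmt(float(m.unique_fraction)))
            me.set("outlier", _fmt(float(m.outlier_fraction)))
            me.set("completeness", _fmt(float(m.completeness)))
            me.set("skewness", _fmt(float(m.skewness)))
            if m.cv is not None:
                me.set("cv", _fmt(float(m.cv)))
            _typed_el(me, "Min", m.observed_min)
            _typed_el(me, "Max", m.observed_max)
            _typed_el(me, "Mode", m.mode)

    rules_el = etree.SubElement(root, "Rules")
    for rule in profile.rules:
        r = etree.SubElement(rules_el, "Rule")
        r.set("id", rule.rule_id)
        r.set("dimension", rule.dimension.value)
        r.set("action", rule.action.value)
        params = dict(rule.params)
        threshold = params.pop("threshold", None)
        if threshold is not None:
            r.set("threshold", _fmt(float(threshold)))
        c = rule.condition
        cond = etree.SubElement(r, "Condition")
        cond.set("missingMin", _fmt(float(c.missing_min)))
        cond.set("missingMax", _fmt(float(c.missing_max)))
        if c.data_type is not None:
            cond.set("dataType", c.data_type.value)
        if c.skew_class is not None:
            cond.set("skewClass", c.skew_class)
        if c.weight_min is not None:
            cond.set("weightMin", _fmt(float(c.weight_min)))
        if c.weight_max is not None:
            cond.set("weightMax", _fmt(float(c.weight_max)))
        if c.mnar is not None:
            cond.set("mnar", _fmt(c.mnar))
        for key in sorted(params):
            p = etree.SubElement(r, "Param")
            p.set("key", key)
            val = params[key]
            if isinstance(val, bool):
                p.set("type", "bool")
            elif isinstance(val, int):
                p.set("type", "int")
            elif isinstance(val, float):
                p.set("type", "float")
            else:
                p.set("type", "str")
            p.set("value", _fmt(val))

    if profile.selected_features is not None:
        feats = etree.SubElement(root, "FederatedFeatures")
        for name in profile.selected_features:
            etree.SubElement(feats, "Feature").set("name", name)

    if profile.workload is not None:
        wl = etree.SubElement(root, "Workload")
        for tag, mapping in (
            ("Config", profile.workload.config),
            ("Realtime", profile.workload.realtime),
        ):
            for key in sorted(mapping):
                el = etree.SubElement(wl, tag)
                el.set("key", key)
                el.set("value", _fmt(mapping[key]))

    doc = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    if path is not None:
        Path(path).write_bytes(doc)
    return doc


def _schema() -> etree.XMLSchema:
    text = resources.files("fdqp").joinpath("schema/dqp.xsd").read_text("utf-8")
    return etree.XMLSchema(etree.fromstring(text.encode()))


_KNOWN_TAGS = {
    "Profile", "Dimensions", "Dimension", "Attributes", "Attribute",
    "Tolerances", "Tolerance", "RuleRefs", "RuleRef", "Measures", "Min",
    "Max", "Mode", "Rules", "Rule", "Condition", "Param",
    "FederatedFeatures", "Feature", "Workload", "Config", "Realtime",
}


def read_profile_xml(
    source: str | bytes | Path, *, validate: bool = True
) -> DQProfile:
    """Parse a profile XML document (bytes/str content, or a file path)."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith(".xml")
    ):
        data = Path(source).read_bytes()
    elif isinstance(source, str):
        data = source.encode("utf-8")
    else:
        data = source
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ProfileError(f"malformed XML: {exc}") from exc
    for el in root.iter():
        if el.tag not in _KNOWN_TAGS:
            raise ProfileError(f"unknown element <{el.tag}>")
    if root.get("version") is None:
        raise ProfileError("Profile element lacks the mandatory version attribute")
    if validate:
        schema = _schema()
        if not schema.validate(root):
            raise ProfileError(f"schema violation: {schema.error_log.last_error}")

    profile = DQProfile(
        version=int(root.get("version")),
        role=ProfileRole(root.get("role", "baseline")),
        node_id=root.get("nodeId"),
        row_count=int(root.get("rowCount", "0")),
    )
    for d in root.iterfind("Dimensions/Dimension"):
        profile.dimensions.add(QualityDimension(d.get("name")))

    measures: dict[str, AttributeMeasures] = {}
    for a in root.iterfind("Attributes/Attribute"):
        spec = AttributeSpec(
            name=a.get("id"),
            data_type=DataType(a.get("dataType", "numeric")),
            weight=float(a.get("weight")) if a.get("weight") else None,
            allowed_min=float(a.get("allowedMin")) if a.get("allowedMin") else None,
            allowed_max=float(a.get("allowedMax")) if a.get("allowedMax") else None,
        )
        for t in a.iterfind("Tolerances/Tolerance"):
            spec.tolerances[QualityDimension(t.get("dimension"))] = float(
                t.get("value")
            )
        for ref in a.iterfind("RuleRefs/RuleRef"):
            spec.rule_ids.append(ref.get("id"))
        me = a.find("Measures")
        if me is not None:
            m = AttributeMeasures(
                missing_fraction=float(me.get("missing", "0")),
                unique_fraction=float(me.get("unique", "0")),
                outlier_fraction=float(me.get("outlier", "0")),
                completeness=float(me.get("completeness", "1")),
                skewness=float(me.get("skewness", "nan")),
                cv=float(me.get("cv")) if me.get("cv") else None,
            )
            for tag, fname in (("Min", "observed_min"), ("Max", "observed_max"),
                               ("Mode", "mode")):
                el = me.find(tag)
                if el is not None:
                    setattr(m, fname, _typed_read(el))
            measures[spec.name] = m
        profile.attributes.append(spec)
    if measures:
        profile.measures = measures

    for r in root.iterfind("Rules/Rule"):
        cond_el = r.find("Condition")
        cond = RuleCondition()
        if cond_el is not None:
            cond = RuleCondition(
                missing_min=float(cond_el.get("missingMin", "0")),
                missing_max=float(cond_el.get("missingMax", "1")),
                data_type=DataType(cond_el.get("dataType"))
                if cond_el.get("dataType")
                else None,
                skew_class=cond_el.get("skewClass"),
                weight_min=float(cond_el.get("weightMin"))
                if cond_el.get("weightMin")
                else None,
                weight_max=float(cond_el.get("weightMax"))
                if cond_el.get("weightMax")
                else None,
                mnar={"true": True, "false": False}.get(cond_el.get("mnar")),
            )
        params: dict[str, Any] = {}
        if r.get("threshold") is not None:
            params["threshold"] = float(r.get("threshold"))
        for p in r.iterfind("Param"):
            params[p.get("key")] = _typed_read(p)
        profile.rules.append(
            QualityRule(
                rule_id=r.get("id"),
                dimension=QualityDimension(r.get("dimension")),
                condition=cond,
                action=RuleAction(r.get("action")),
                params=params,
            )
        )

    feats = root.find("FederatedFeatures")
    if feats is not None:
        profile.selected_features = [f.get("name") for f in feats.iterfind("Feature")]

    wl = root.find("Workload")
    if wl is not None:
        stub = WorkloadStub()
        for el in wl:
            target = stub.config if el.tag == "Config" else stub.realtime
            target[el.get("key")] = el.get("value")
        profile.workload = stub
    return profile


# ---------------------------------------------------------------------------
# Delta exchange (diff / apply patch algebra)
# ---------------------------------------------------------------------------

def _to_plain(obj: Any) -> Any:
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, (DQProfile, AttributeSpec, AttributeMeasures, QualityRule,
                        RuleCondition, WorkloadStub)):
        return {
            "__class__": type(obj).__name__,
            **{k: _to_plain(v) for k, v in vars(obj).items()},
        }
    if isinstance(obj, dict):
        return {
            (k.value if isinstance(k, Enum) else k): _to_plain(v)
            for k, v in obj.items()
        }
    if isinstance(obj, set):
        return sorted(_to_plain(x) for x in obj)
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    return obj


_CLASSES = {
    "DQProfile": DQProfile,
    "AttributeSpec": AttributeSpec,
    "AttributeMeasures": AttributeMeasures,
    "QualityRule": QualityRule,
    "RuleCondition": RuleCondition,
    "WorkloadStub": WorkloadStub,
}

_ENUM_FIELDS = {
    ("DQProfile", "role"): ProfileRole,
    ("AttributeSpec", "data_type"): DataType,
    ("QualityRule", "dimension"): QualityDimension,
    ("QualityRule", "action"): RuleAction,
    ("RuleCondition", "data_type"): DataType,
}


def _from_plain(obj: Any) -> Any:
    if isinstance(obj, dict) and "__class__" in obj:
        cname = obj["__class__"]
        cls = _CLASSES[cname]
        kwargs = {}
        for k, v in obj.items():
            if k == "__class__":
                continue
            enum_cls = _ENUM_FIELDS.get((cname, k))
            if enum_cls is not None and v is not None:
                kwargs[k] = enum_cls(v)
            elif cname == "DQProfile" and k == "dimensions":
                kwargs[k] = {QualityDimension(x) for x in v}
            elif cname == "DQProfile" and k == "measures" and v is not None:
                kwargs[k] = {name: _from_plain(m) for name, m in v.items()}
            elif cname == "AttributeSpec" and k == "tolerances":
                kwargs[k] = {QualityDimension(d): t for d, t in v.items()}
            else:
                kwargs[k] = _from_plain(v)
        return cls(**kwargs)
    if isinstance(obj, dict):
        return {k: _from_plain(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_from_plain(x) for x in obj]
    return obj


def _flatten(obj: Any, prefix: str, out: dict[str, Any]) -> None:
    if isinstance(obj, dict):
        out[f"{prefix}/__keys"] = sorted(obj)
        for k in obj:
            _flatten(obj[k], f"{prefix}/{k}", out)
    elif isinstance(obj, list):
        out[f"{prefix}/__len"] = len(obj)
        for i, item in enumerate(obj):
            _flatten(item, f"{prefix}/{i}", out)
    else:
        out[prefix] = obj


def _profile_flat(profile: DQProfile) -> dict[str, Any]:
    out: dict[str, Any] = {}
    _flatten(_to_plain(profile), "", out)
    return out


def _unflatten(flat: Mapping[str, Any]) -> Any:
    def build(prefix: str) -> Any:
        if f"{prefix}/__keys" in flat:
            return {k: build(f"{prefix}/{k}") for k in flat[f"{prefix}/__keys"]}
        if f"{prefix}/__len" in flat:
            return [build(f"{prefix}/{i}") for i in range(flat[f"{prefix}/__len"])]
        return flat[prefix]

    return build("")


def diff_profiles(old: DQProfile, new: DQProfile) -> ProfileDelta:
    """Compute the exact field-level patch taking *old* to *new*."""
    if old.version > new.version:
        raise ProfileError(
            f"cannot diff towards an older version ({old.version} -> {new.version})"
        )
    flat_old = _profile_flat(old)
    flat_new = _profile_flat(new)
    changed: list[tuple[str, Any, Any]] = []
    for path in sorted(set(flat_old) | set(flat_new)):
        a = flat_old.get(path, _ABSENT)
        b = flat_new.get(path, _ABSENT)
        if a != b or type(a) is not type(b):
            changed.append((path, a, b))
    return ProfileDelta(
        version_from=old.version, version_to=new.version, changed_fields=changed
    )


def apply_delta(old: DQProfile, delta: ProfileDelta) -> DQProfile:
    """Apply *delta* to *old*, reproducing the target profile exactly."""
    if old.version != delta.version_from:
        raise ProfileError(
            f"delta expects source version {delta.version_from}, "
            f"profile has {old.version}"
        )
    flat = _profile_flat(old)
    for path, _old_val, new_val in delta.changed_fields:
        if isinstance(new_val, str) and new_val == _ABSENT:
            flat.pop(path, None)
        else:
            flat[path] = new_val
    return _from_plain(_unflatten(flat))


def profiles_equal(a: DQProfile, b: DQProfile, tol: float = 1e-9) -> bool:
    """Structural equality with *tol* slack on numeric fields (NaN == NaN)."""
    fa, fb = _profile_flat(a), _profile_flat(b)
    if set(fa) != set(fb):
        return False
    for path, va in fa.items():
        vb = fb[path]
        if isinstance(va, float) and isinstance(vb, float):
            if math.isnan(va) and math.isnan(vb):
                continue
            if abs(va - vb) > tol:
                return False
        elif va != vb:
            return False
    return True
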