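"""Model bundles: tabular formats, validation, the bundled toy fixture.

A model bundle is a directory with

* ``reactions.tsv`` — id, stoichiometry (``met:coeff;met:coeff``),
  lower_bound, upper_bound, tag
* ``enzymes.tsv`` — id, kcats (``reaction:kcat;...``), e_min, e_max, tag
* ``pools.tsv`` — key/value rows: ``pool_max`` and ``special:<role>``
  entries naming the growth, NGAM, damage-exchange and exchange
  reactions
* ``boolean.rules`` — the signalling network (see :mod:`agesim.boolean`)
* ``regulation.tsv`` — tf, enzyme, sign (+1/-1)
* ``config.yaml`` — simulation parameters (see :class:`SimParams`)

The tabular dialect is the canonical source of truth; SBML import (via
cobra, optional) maps species and reactions only, since ecFBA
annotations are not standardised in SBML.  The ``tag`` columns carry a
free provenance label per entry so that a transcribed published model
can report how many components each extension added.

:func:`build_toy_fixture` writes a reduced central-carbon + ROS network
(glucose uptake, lumped glycolysis, fermentation, respiration with
electron leakage into superoxide, H2O2 detoxification, ethanol
oxidation, biomass, NGAM) with a matching 11-component Boolean net and
regulation table.  Its output is deterministic and byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .boolean import BooleanNetwork, parse_rules
from .dynamics import SimParams
from .ecfba import Enzyme, MetabolicModel, Reaction
from .regulation import InputThresholds, RegulationTable

logger = logging.getLogger(__name__)

__all__ = ["ModelBundle", "load_bundle", "write_bundle",
           "build_toy_fixture", "structural_summary", "parse_config",
           "load_sbml_stoichiometry"]


class BundleError(ValueError):
    """A bundle file is missing, malformed or has dangling references."""


@dataclass(frozen=True)
class ModelBundle:
    model: MetabolicModel
    network: BooleanNetwork
    table: RegulationTable
    params: SimParams

    @property
    def summary(self) -> dict:
        return structural_summary(self.model, self.network, self.table)


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_pairs(text: str, context: str) -> dict[str, float]:
    pairs = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise BundleError(f"{context}: bad pair {item!r}")
        key, value = item.rsplit(":", 1)
        try:
            pairs[key.strip()] = float(value)
        except ValueError:
            raise BundleError(f"{context}: bad number in {item!r}")
    return pairs


def _fmt_pairs(pairs: dict[str, float]) -> str:
    return ";".join(f"{k}:{v:g}" for k, v in pairs.items())


def _read_tsv(path: Path, required: list[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise BundleError(f"missing file {path}")
    lines = path.read_text().splitlines()
    rows = []
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            for col in required:
                if col not in header:
                    raise BundleError(f"{path}: missing column {col!r}")
            continue
        if len(fields) < len(header):
            fields += [""] * (len(header) - len(fields))
        rows.append(dict(zip(header, (f.strip() for f in fields))))
        rows[-1]["_line"] = str(lineno)
    if header is None:
        raise BundleError(f"{path}: empty file")
    return rows


# ---------------------------------------------------------------------------
# bundle load / write

def load_metabolic_model(path: Path) -> MetabolicModel:
    path = Path(path)
    reactions = []
    for row in _read_tsv(path / "reactions.tsv",
                         ["id", "stoichiometry", "lower_bound", "upper_bound"]):
        ctx = f"{path / 'reactions.tsv'} line {row['_line']}"
        reactions.append(Reaction(
            id=row["id"],
            stoichiometry=_parse_pairs(row["stoichiometry"], ctx),
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            tag=row.get("tag") or "core",
        ))
    enzymes = []
    for row in _read_tsv(path / "enzymes.tsv",
                         ["id", "kcats", "e_min", "e_max"]):
        ctx = f"{path / 'enzymes.tsv'} line {row['_line']}"
        enzymes.append(Enzyme(
            id=row["id"],
            kcats=_parse_pairs(row["kcats"], ctx),
            e_min=float(row["e_min"]),
            e_max=float(row["e_max"]),
            tag=row.get("tag") or "core",
        ))
    pool_max = None
    specials = {}
    for row in _read_tsv(path / "pools.tsv", ["key", "value"]):
        key, value = row["key"], row["value"]
        if key == "pool_max":
            pool_max = float(value)
        elif key.startswith("special:"):
            specials[key[len("special:"):]] = value
        else:
            raise BundleError(
                f"{path / 'pools.tsv'} line {row['_line']}: unknown key {key!r}")
    if pool_max is None:
        raise BundleError(f"{path / 'pools.tsv'}: pool_max not set")
    metabolites = sorted({m for r in reactions for m in r.stoichiometry})
    try:
        return MetabolicModel(tuple(metabolites), tuple(reactions),
                              tuple(enzymes), pool_max, specials)
    except ValueError as err:
        raise BundleError(f"{path}: {err}")


def load_regulation_table(path: Path) -> RegulationTable:
    entries: dict[str, set[tuple[str, int]]] = {}
    for row in _read_tsv(Path(path), ["tf", "enzyme", "sign"]):
        sign = int(row["sign"])
        pair = (row["enzyme"], sign)
        bucket = entries.setdefault(row["tf"], set())
        if any(enz == row["enzyme"] for enz, _ in bucket):
            raise BundleError(
                f"{path} line {row['_line']}: duplicate pair "
                f"({row['tf']}, {row['enzyme']})")
        bucket.add(pair)
    return RegulationTable({tf: frozenset(v) for tf, v in entries.items()})


def parse_config(raw: dict) -> SimParams:
    """Build :class:`SimParams` from a config mapping (YAML-friendly)."""
    raw = dict(raw or {})
    thresholds = InputThresholds(**raw.pop("thresholds", {}))
    if "trx_enzymes" in raw:
        raw["trx_enzymes"] = tuple(raw["trx_enzymes"])
    known = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(raw) - known
    if unknown:
        raise BundleError(f"unknown config keys {sorted(unknown)}")
    return SimParams(thresholds=thresholds, **raw)


def load_bundle(path: str | Path) -> ModelBundle:
    """Load and cross-validate a model bundle directory.

    All cross-references are checked (regulation TFs must be Boolean
    components, regulated enzymes must exist in the metabolic model) and
    a structural summary is logged.
    """
    path = Path(path)
    if not path.is_dir():
        raise BundleError(f"bundle directory {path} does not exist")
    model = load_metabolic_model(path)
    rules_path = path / "boolean.rules"
    if not rules_path.exists():
        raise BundleError(f"missing file {rules_path}")
    network = parse_rules(rules_path.read_text())
    table = load_regulation_table(path / "regulation.tsv")
    try:
        table.validate_against(network, model)
    except ValueError as err:
        raise BundleError(f"{path / 'regulation.tsv'}: dangling reference: {err}")
    config_path = path / "config.yaml"
    config = yaml.safe_load(config_path.read_text()) if config_path.exists() else {}
    params = parse_config(config)
    bundle = ModelBundle(model, network, table, params)
    logger.info("loaded bundle %s: %s", path, bundle.summary)
    return bundle


def structural_summary(model: MetabolicModel, network: BooleanNetwork,
                       table: RegulationTable) -> dict:
    """Component/rule/flux/enzyme counts, total and per provenance tag."""
    def by_tag(items, tag_of):
        out: dict[str, int] = {}
        for item in items:
            tag = tag_of(item)
            out[tag] = out.get(tag, 0) + 1
        return out

    rule_targets = [t for t in network.components if t not in network.inputs]
    met_tags: dict[str, str] = {}
    for r in model.reactions:  # a metabolite inherits the tag introducing it
        for m in r.stoichiometry:
            met_tags.setdefault(m, r.tag)
    return {
        "boolean_components": len(network.components),
        "boolean_components_by_tag": by_tag(
            network.components, lambda c: network.tags.get(c, "core")),
        "boolean_rules": len(rule_targets),
        "boolean_rules_by_tag": by_tag(
            rule_targets, lambda c: network.tags.get(c, "core")),
        "fluxes": len(model.reactions),
        "fluxes_by_tag": by_tag(model.reactions, lambda r: r.tag),
        "metabolites": len(model.metabolites),
        "metabolites_by_tag": by_tag(model.metabolites, met_tags.get),
        "enzymes": len(model.enzymes),
        "enzymes_by_tag": by_tag(model.enzymes, lambda e: e.tag),
        "regulation_pairs": sum(len(v) for v in table.entries.values()),
    }


def write_bundle(path: str | Path, model: MetabolicModel,
                 network_rules: str, table: RegulationTable,
                 params: SimParams | None = None) -> Path:
    """Write a bundle directory (deterministic formatting)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = ["id\tstoichiometry\tlower_bound\tupper_bound\ttag"]
    for r in model.reactions:
        lines.append(f"{r.id}\t{_fmt_pairs(r.stoichiometry)}\t"
                     f"{r.lower_bound:g}\t{r.upper_bound:g}\t{r.tag}")
    (path / "reactions.tsv").write_text("\n".join(lines) + "\n")
    lines = ["id\tkcats\te_min\te_max\ttag"]
    for e in model.enzymes:
        lines.append(f"{e.id}\t{_fmt_pairs(e.kcats)}\t"
                     f"{e.e_min:g}\t{e.e_max:g}\t{e.tag}")
    (path / "enzymes.tsv").write_text("\n".join(lines) + "\n")
    lines = ["key\tvalue", f"pool_max\t{model.pool_max:g}"]
    for role in sorted(model.specials):
        lines.append(f"special:{role}\t{model.specials[role]}")
    (path / "pools.tsv").write_text("\n".join(lines) + "\n")
    (path / "boolean.rules").write_text(network_rules)
    lines = ["tf\tenzyme\tsign"]
    for tf in sorted(table.entries):
        for enzyme, sign in sorted(table.entries[tf]):
            lines.append(f"{tf}\t{enzyme}\t{sign:+d}")
    (path / "regulation.tsv").write_text("\n".join(lines) + "\n")
    if params is not None:
        cfg = dataclasses.asdict(params)
        cfg["thresholds"] = dataclasses.asdict(params.thresholds)
        cfg["trx_enzymes"] = list(params.trx_enzymes)
        (path / "config.yaml").write_text(
            yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False))
    return path


# ---------------------------------------------------------------------------
# toy fixture

#: Boolean rules of the reduced signalling net: glucose sensing feeding
#: PKA/Snf1-like switches, plus the oxidative-stress block (Sln1->Skn7,
#: Yap1 inhibited by thioredoxin, Trx crosstalk to Msn2/4).
TOY_RULES = """\
# Reduced nutrient/oxidative-stress signalling network (toy fixture)
#tag core
INPUT: Glucose, H2O2, Trx12
PKA = Glucose
Snf1 = !Glucose
Cat8 = Snf1
Rim15 = !PKA
Msn2/4 = !PKA | Trx12
#tag oxidative-stress
Sln1 = H2O2
Skn7 = Sln1
Yap1 = H2O2 & !Trx12
"""

TOY_REGULATION = {
    "Yap1": frozenset({("Sod1", 1), ("Ctt1", 1), ("Trx1", 1)}),
    "Skn7": frozenset({("Sod1", 1), ("Trx1", 1)}),
    "Msn2/4": frozenset({("Ctt1", 1)}),
    "Cat8": frozenset({("Adh2", 1)}),
    "PKA": frozenset({("Adh2", -1), ("Cit1", -1)}),
}


def build_toy_model(leakage: float = 1.0, pool_max: float = 0.018,
                    basal_ngam: float = 0.01) -> MetabolicModel:
    """Reduced central-carbon + ROS network used by the bundled fixture.

    Design (documented in docs/methods.md): cytosolic ATP for growth is
    cheapest per unit enzyme via fermentation, so a young cell with a
    large pool ferments maximally.  The NGAM maintenance demand draws on
    mitochondrial ATP, produced only by oxidative routes — respiring the
    fermentation by-product ethanol (enzyme-cheapest) or pyruvate
    (glucose-cheapest, used when the chemostat minimises glucose) — so a
    rising maintenance load recruits oxygen consumption and, once
    fermentation ebbs with the growth rate, turns the net ethanol
    exchange into uptake.  Oxidative routes leak ``leakage`` superoxide
    (in damage-equivalent pseudo-units) per unit flux; superoxide's
    uncatalysed fate is hydroxyl radical and protein damage unless
    detoxifying capacity has been forced by stress regulation.
    Oxidising damage costs ATP, so free detox capacity is always used.
    """
    lam = leakage
    reactions = [
        # --- core central-carbon backbone -------------------------------
        Reaction("GLC_UP", {"glc": 1}, 0, 1000),
        Reaction("GLYC", {"glc": -1, "pyr": 2, "atp_c": 2}, 0, 1000),
        Reaction("FERM", {"pyr": -1, "etoh": 1, "co2": 1}, 0, 1000),
        Reaction("RESP", {"pyr": -1, "o2": -2.4, "co2": 2.8, "ac": 0.2,
                          "atp_m": 9, "sox": lam}, 0, 1000),
        Reaction("ETOH_RESP", {"etoh": -1, "o2": -2.9, "co2": 1.9,
                               "ac": 0.1, "atp_m": 8, "sox": 0.5 * lam},
                 0, 1000),
        Reaction("ANT", {"atp_m": -1, "atp_c": 1}, 0, 1000),
        Reaction("O2_UP", {"o2": 1}, 0, 1000),
        Reaction("GROWTH", {"glc": -1, "atp_c": -3}, 0, 1000),
        Reaction("NGAM", {"atp_m": -1}, basal_ngam, 1000),
        # unspecified cytosolic ATPase activity: lets glycolytic ATP be
        # dissipated when growth cannot absorb it (e.g. slow chemostats)
        Reaction("ATPASE_C", {"atp_c": -1}, 0, 1000),
        Reaction("EX_ETOH", {"etoh": -1}, -1, 1000),
        Reaction("EX_AC", {"ac": -1}, 0, 1000),
        Reaction("EX_CO2", {"co2": -1}, 0, 1000),
        # --- ROS/RNS block ----------------------------------------------
        Reaction("SOD", {"sox": -1, "h2o2": 0.5}, 0, 1000, tag="ros"),
        Reaction("RNS", {"sox": -1, "oh": 1}, 0, 1000, tag="ros"),
        Reaction("TRX", {"h2o2": -1}, 0, 1000, tag="ros"),
        Reaction("CTT", {"h2o2": -1}, 0, 1000, tag="ros"),
        Reaction("FENTON", {"h2o2": -1, "oh": 1}, 0, 1000, tag="ros"),
        Reaction("OXD", {"oh": -1, "atp_c": -0.1, "dmg": 1}, 0, 1000,
                 tag="ros"),
        Reaction("EX_DMG", {"dmg": -1}, 0, 1000, tag="ros"),
    ]
    enzymes = [
        Enzyme("Hxt1", {"GLC_UP": 100}, 0, pool_max),
        Enzyme("Pfk1", {"GLYC": 100}, 0, pool_max),
        Enzyme("Adh1", {"FERM": 200}, 0, pool_max),
        Enzyme("Cit1", {"RESP": 5}, 0, pool_max),
        Enzyme("Adh2", {"ETOH_RESP": 16}, 0, pool_max),
        Enzyme("Ant1", {"ANT": 50}, 0, pool_max),
        Enzyme("Sod1", {"SOD": 20}, 0, pool_max, tag="ros"),
        Enzyme("Trx1", {"TRX": 10}, 0, pool_max, tag="ros"),
        Enzyme("Ctt1", {"CTT": 20}, 0, pool_max, tag="ros"),
    ]
    metabolites = sorted({m for r in reactions for m in r.stoichiometry})
    specials = {
        "growth": "GROWTH",
        "ngam": "NGAM",
        "damage_exchange": "EX_DMG",
        "glucose_uptake": "GLC_UP",
        "ethanol_exchange": "EX_ETOH",
        "o2_uptake": "O2_UP",
        "co2_exchange": "EX_CO2",
        "acetate_exchange": "EX_AC",
    }
    return MetabolicModel(tuple(metabolites), tuple(reactions),
                          tuple(enzymes), pool_max, specials)


def build_toy_fixture(path: str | Path, leakage: float = 1.0) -> Path:
    """Write the bundled toy fixture to ``path`` (byte-deterministic)."""
    model = build_toy_model(leakage=leakage)
    table = RegulationTable(TOY_REGULATION)
    params = SimParams()
    return write_bundle(path, model, TOY_RULES, table, params)


def toy_bundle(leakage: float = 1.0) -> ModelBundle:
    """In-memory toy fixture (identical content to the on-disk bundle)."""
    return ModelBundle(build_toy_model(leakage=leakage),
                       parse_rules(TOY_RULES),
                       RegulationTable(TOY_REGULATION), SimParams())


def load_sbml_stoichiometry(path: str | Path):
    """Import species/reactions from an SBML file (requires cobra).

    Only the stoichiometric part is mapped; enzymes, kcats and the pool
    stay in the tabular dialect.  Returns (metabolites, reactions).
    """
    try:
        import cobra.io
    except ImportError as err:  # pragma: no cover
        raise ImportError("SBML import requires the optional cobra "
                          "dependency (pip install agesim[sbml])") from err
    sbml = cobra.io.read_sbml_model(str(path))
    metabolites = tuple(sorted(m.id for m in sbml.metabolites))
    reactions = tuple(
        Reaction(r.id, {m.id: coeff for m, coeff in r.metabolites.items()},
                 r.lower_bound, r.upper_bound, tag="sbml")
        for r in sbml.reactions)
    return metabolites, reactions
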