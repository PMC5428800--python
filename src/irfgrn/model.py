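"""Logic-gated Petri-net models of transcription-factor regulatory networks.

A model is a bipartite graph of *places* (gene transcripts, DNA elements,
output genes, biological processes) and *transitions* (molecular interactions).
Transitions are pure AND gates over their activating inputs; OR logic is
expressed structurally as parallel transitions into the same place, and
inhibition is an arc kind on a transition, not a place attribute.

The bundled default model is the interferon-regulatory-factor (IRF) network
of human Langerhans cells: entry transcription factors IRF1/IRF4/IRF8, their
AP-1 and ETS binding partners, the composite DNA elements ISRE/EICE/AICE, the
Programme A and Programme B output genes, and six process outputs (Th1, Th2,
Th17 polarisation, class I/II antigen presentation, phagocytosis).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

PLACE_CLASSES = (
    "transcription_factor",
    "complex",
    "dna_element",
    "output_gene",
    "process_output",
)
ENTRY_GROUPS = ("IRF1", "IRF4", "IRF8", "AP1", "ETS", "none")
GATES = ("and", "or", "inhibition")
DNA_ELEMENTS = ("ISRE", "EICE", "AICE")
#: family names that expand to every roster member of that entry group
FAMILY_NAMES = ("AP1", "ETS")


class ModelFormatError(ValueError):
    """Raised for malformed model or interaction files (carries line numbers)."""


@dataclass(frozen=True)
class Place:
    """One network entity (gene transcript, DNA element or process output)."""

    id: str
    label: str = ""
    klass: str = "transcription_factor"
    entry_group: str = "none"
    is_entry: bool = False
    is_output: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValueError("place id must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.id)
        if self.klass not in PLACE_CLASSES:
            raise ValueError(
                f"place {self.id!r}: unknown klass {self.klass!r}; "
                f"allowed: {', '.join(PLACE_CLASSES)}"
            )
        if self.entry_group not in ENTRY_GROUPS:
            raise ValueError(
                f"place {self.id!r}: unknown entry_group {self.entry_group!r}"
            )
        if self.is_entry and self.klass != "transcription_factor":
            raise ValueError(
                f"place {self.id!r}: entry places must be transcription factors"
            )
        if self.is_output and self.klass not in ("output_gene", "process_output"):
            raise ValueError(
                f"place {self.id!r}: output places must be output genes "
                "or process outputs"
            )


@dataclass(frozen=True)
class Transition:
    """One interaction: an AND gate over activating inputs.

    Inhibitory inputs reduce the token flow through the transition (see the
    simulation engine); they never gate it structurally.
    """

    id: str
    activating_inputs: tuple[str, ...]
    inhibitory_inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "activating_inputs", tuple(self.activating_inputs))
        object.__setattr__(self, "inhibitory_inputs", tuple(self.inhibitory_inputs))
        object.__setattr__(self, "outputs", tuple(self.outputs))
        if not self.id:
            raise ValueError("transition id must be non-empty")
        if len(self.activating_inputs) < 1:
            raise ValueError(f"transition {self.id!r}: needs >=1 activating input")
        if len(self.outputs) < 1:
            raise ValueError(f"transition {self.id!r}: needs >=1 output")
        if len(set(self.activating_inputs)) != len(self.activating_inputs):
            raise ValueError(f"transition {self.id!r}: duplicate activating input")
        overlap = set(self.activating_inputs) & set(self.inhibitory_inputs)
        if overlap:
            raise ValueError(
                f"transition {self.id!r}: place(s) {sorted(overlap)} appear as "
                "both activating and inhibitory inputs"
            )


@dataclass
class PetriNetModel:
    """Bipartite logic-gated network: places, transitions and free metadata."""

    places: list[Place]
    transitions: list[Transition]
    metadata: dict[str, str] = field(default_factory=dict)
    _index: dict[str, Place] = field(
        default_factory=dict, init=False, repr=False, compare=False
    )

    def __post_init__(self):
        self._index = {}
        for p in self.places:
            if p.id in self._index:
                raise ValueError(f"duplicate place id {p.id!r}")
            self._index[p.id] = p
        seen_t: set[str] = set()
        for t in self.transitions:
            if t.id in seen_t:
                raise ValueError(f"duplicate transition id {t.id!r}")
            seen_t.add(t.id)

    @property
    def name(self) -> str:
        return self.metadata.get("name", "unnamed")

    def place(self, place_id: str) -> Place:
        return self._index[place_id]

    def __contains__(self, place_id: str) -> bool:
        return place_id in self._index

    @property
    def entry_places(self) -> list[Place]:
        return [p for p in self.places if p.is_entry]

    @property
    def output_places(self) -> list[Place]:
        return [p for p in self.places if p.is_output]

    def places_in_group(self, group: str) -> list[Place]:
        return [p for p in self.places if p.entry_group == group and p.is_entry]


@dataclass(frozen=True)
class InteractionRecord:
    """One curated Boolean interaction row from the literature database.

    ``partner_b`` may be a place id or a family name (``AP1``/``ETS``) which
    expands to every entry-flagged roster member of that family.  Records
    backed by fewer than two independent reports are dropped at compile time.
    """

    partner_a: str
    partner_b: str | None
    gate: str
    dna_element: str | None
    targets: tuple[str, ...]
    evidence_count: int = 2

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.gate not in GATES:
            raise ValueError(
                f"unknown gate {self.gate!r}; allowed gates: {', '.join(GATES)}"
            )
        if self.gate == "and" and not self.partner_b:
            raise ValueError("gate 'and' requires partner_b")
        if not self.targets:
            raise ValueError("interaction record needs >=1 target")
        if self.evidence_count < 0:
            raise ValueError("evidence_count must be >= 0")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# compilation


def _expand_partner(name: str, model_index: dict[str, Place], families) -> list[str]:
    if name in FAMILY_NAMES:
        members = families.get(name, [])
        if not members:
            raise ValueError(f"family {name!r} has no entry members in the roster")
        return members
    if name not in model_index:
        raise ValueError(f"unresolved id {name!r}: not in roster")
    return [name]


def compile_interactions(
    records: list[InteractionRecord],
    roster: list[Place],
    evidence_threshold: int = 2,
    metadata: dict[str, str] | None = None,
) -> PetriNetModel:
    """Compile curated Boolean interaction records into a Petri net.

    ``and`` records yield one transition per partner pair (family partners
    expand member-wise); ``or`` records yield parallel single-partner
    transitions; records naming a DNA element are realised as a two-stage path
    partners -> element -> each target (element->target arcs deduplicated
    across records); ``inhibition`` records attach the inhibitor as an
    inhibitory input to every transition feeding the listed targets.
    """
    if not records:
        raise ValueError("empty record list")
    if not roster:
        raise ValueError("empty roster: no ids can resolve")
    index = {p.id: p for p in roster}
    if len(index) != len(roster):
        raise ValueError("duplicate place ids in roster")
    families = {
        fam: [p.id for p in roster if p.entry_group == fam and p.is_entry]
        for fam in FAMILY_NAMES
    }

    # keyed by (sorted activating inputs, sorted outputs) for deduplication
    trans: dict[tuple[tuple[str, ...], tuple[str, ...]], set[str]] = {}
    inhibitions: list[tuple[list[str], set[str]]] = []

    def add(acts: tuple[str, ...], outs: tuple[str, ...]):
        key = (tuple(sorted(acts)), tuple(sorted(outs)))
        trans.setdefault(key, set())

    for rec in records:
        if rec.evidence_count < evidence_threshold:
            logger.warning(
                "dropping interaction %s/%s -> %s: %d report(s) < %d required",
                rec.partner_a, rec.partner_b, rec.targets,
                rec.evidence_count, evidence_threshold,
            )
            continue
        targets = []
        for t in rec.targets:
            if t not in index:
                raise ValueError(f"unresolved id {t!r}: not in roster")
            targets.append(t)
        a_ids = _expand_partner(rec.partner_a, index, families)
        if rec.gate == "inhibition":
            inhibitions.append((a_ids, set(targets)))
            continue
        b_ids = (
            _expand_partner(rec.partner_b, index, families) if rec.partner_b else []
        )
        if rec.gate == "and":
            input_sets = [(a, b) for a in a_ids for b in b_ids]
        else:  # "or": any single partner suffices
            input_sets = [(a,) for a in a_ids] + [(b,) for b in b_ids]
        element = rec.dna_element
        if element is not None:
            if element not in index:
                raise ValueError(f"unresolved id {element!r}: not in roster")
            for acts in input_sets:
                add(acts, (element,))
            for t in targets:
                add((element,), (t,))
        else:
            for acts in input_sets:
                add(acts, tuple(targets))

    for inhibitor_ids, targets in inhibitions:
        hit = False
        for (acts, outs) in list(trans):
            if targets & set(outs):
                hit = True
                for i in inhibitor_ids:
                    if i in acts:
                        raise ValueError(
                            f"inhibitor {i!r} is an activating input of a "
                            "transition it would inhibit"
                        )
                    trans[(acts, outs)].add(i)
        if not hit:
            logger.warning(
                "inhibition of %s by %s matched no transition",
                sorted(targets), inhibitor_ids,
            )

    transitions = [
        Transition(
            id="t_" + "+".join(acts) + "__" + "+".join(outs),
            activating_inputs=acts,
            inhibitory_inputs=tuple(sorted(inh)),
            outputs=outs,
        )
        for (acts, outs), inh in sorted(trans.items())
    ]
    return PetriNetModel(list(roster), transitions, dict(metadata or {}))


# ---------------------------------------------------------------------------
# the bundled IRF-GRN

AP1_PARTNERS = ("JUN", "FOS", "BATF", "BATF3")
ETS_PARTNERS = (
    "ELF1", "ELF4", "ELK1", "ELK3", "ETS1", "ETS2",
    "EHF", "ELF2", "ETV3", "ETV6", "GABPA",
)
PROGRAMME_A_GENES = (
    "CAV1", "ERAP1", "ERAP2", "TAP1", "HLA_I_B2M", "TAP2", "TAPBPL",
    "PSME1", "PSME2", "PSMB10", "CYBB", "CD40_CD80_CD86", "IL15",
    "IL12p40", "IFNb", "iNOS", "IL18",
)
PROGRAMME_B_GENES = ("IL10", "IL33", "CD74", "LYZ", "CIITA", "PRDM1")
PROCESS_OUTPUTS = (
    "Th1", "Th2", "Th17",
    "antigen_presentation_class_I", "antigen_presentation_class_II",
    "phagocytosis",
)
_GROUPED_LABELS = {
    "HLA_I_B2M": "(HLA A-F, B2M)",
    "CD40_CD80_CD86": "(CD40, CD80, CD86)",
}


def default_roster() -> list[Place]:
    places = [
        Place("IRF1", klass="transcription_factor", entry_group="IRF1", is_entry=True),
        Place("IRF8", klass="transcription_factor", entry_group="IRF8", is_entry=True),
        Place("IRF4", klass="transcription_factor", entry_group="IRF4", is_entry=True),
    ]
    places += [
        Place(g, klass="transcription_factor", entry_group="AP1", is_entry=True)
        for g in AP1_PARTNERS
    ]
    places += [
        Place(g, klass="transcription_factor", entry_group="ETS", is_entry=True)
        for g in ETS_PARTNERS
    ]
    places += [Place(e, klass="dna_element") for e in DNA_ELEMENTS]
    places += [
        Place(g, label=_GROUPED_LABELS.get(g, g), klass="output_gene", is_output=True)
        for g in PROGRAMME_A_GENES + PROGRAMME_B_GENES
    ]
    places += [Place(p, klass="process_output", is_output=True) for p in PROCESS_OUTPUTS]
    return places


def default_interactions() -> list[InteractionRecord]:
    """The curated wiring of the bundled IRF-GRN.

    IRF1 alone drives ISRE; IRF8 requires an ETS partner at ISRE; IRF4
    requires an ETS partner at EICE or an AP-1 partner at AICE.  ISRE
    transcribes the Programme A genes (feeding Th1, class I antigen
    presentation, phagocytosis), EICE the Programme B genes (Th2, class II),
    and AICE drives Th17.
    """
    records = [
        InteractionRecord("IRF1", None, "or", "ISRE", PROGRAMME_A_GENES),
        InteractionRecord("IRF8", "ETS", "and", "ISRE", PROGRAMME_A_GENES),
        InteractionRecord("IRF4", "ETS", "and", "EICE", PROGRAMME_B_GENES),
        InteractionRecord("IRF4", "AP1", "and", "AICE", ("Th17",)),
    ]
    a_fx = ("Th1", "antigen_presentation_class_I", "phagocytosis")
    b_fx = ("Th2", "antigen_presentation_class_II")
    records += [InteractionRecord(g, None, "or", None, a_fx) for g in PROGRAMME_A_GENES]
    records += [InteractionRecord(g, None, "or", None, b_fx) for g in PROGRAMME_B_GENES]
    return records


def build_default_irf_grn() -> PetriNetModel:
    """Compile and return the bundled Langerhans-cell IRF-GRN."""
    metadata = {
        "name": "irf-grn-default",
        "description": (
            "IRF1/IRF4/IRF8 regulatory network of human Langerhans cells with "
            "AP-1 and ETS partners, ISRE/EICE/AICE DNA elements, Programme A/B "
            "output genes and six functional outputs"
        ),
        "programme_A": ",".join(PROGRAMME_A_GENES),
        "programme_B": ",".join(PROGRAMME_B_GENES),
    }
    return compile_interactions(default_interactions(), default_roster(),
                                metadata=metadata)


# ---------------------------------------------------------------------------
# validation


def validate_model(model: PetriNetModel) -> ValidationReport:
    """Check structural invariants; unreachable outputs are warnings."""
    report = ValidationReport()
    place_ids = {p.id for p in model.places}
    for t in model.transitions:
        if t.id in place_ids:
            report.errors.append(f"transition {t.id!r}: id collides with a place")
        for pid in (*t.activating_inputs, *t.inhibitory_inputs, *t.outputs):
            if pid not in place_ids:
                report.errors.append(
                    f"transition {t.id!r}: references unknown place {pid!r}"
                )
    if report.errors:
        return report
    # reachability from all entries ON, ignoring inhibition
    from .oracle import forward_closure

    on = forward_closure(model, {p.id for p in model.entry_places})
    for p in model.output_places:
        if p.id not in on:
            report.warnings.append(
                f"output place {p.id!r} unreachable from any entry place"
            )
    if not model.entry_places:
        report.warnings.append("model has no entry places")
    return report


# ---------------------------------------------------------------------------
# model TSV dialect

_PLACE_COLS = 6
_TRANS_COLS = 4


def _bool_field(value: str, lineno: int) -> bool:
    if value == "1":
        return True
    if value == "0":
        return False
    raise ModelFormatError(f"line {lineno}: boolean field must be 0 or 1, got {value!r}")


def write_model(model: PetriNetModel, path) -> None:
    """Write the two-section tab-separated model dialect (canonical form)."""
    lines = []
    for key in sorted(model.metadata):
        lines.append(f"#!{key}\t{model.metadata[key]}")
    lines.append("#PLACES")
    for p in model.places:
        lines.append("\t".join([
            p.id, p.label, p.klass, p.entry_group,
            "1" if p.is_entry else "0", "1" if p.is_output else "0",
        ]))
    lines.append("")
    lines.append("#TRANSITIONS")
    for t in model.transitions:
        lines.append("\t".join([
            t.id,
            ",".join(t.activating_inputs),
            ",".join(t.inhibitory_inputs) or "-",
            ",".join(t.outputs),
        ]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_model(path) -> PetriNetModel:
    """Read a model TSV written by :func:`write_model` (or by hand)."""
    places: list[Place] = []
    transitions: list[Transition] = []
    metadata: dict[str, str] = {}
    section = None
    seen_places: set[str] = set()
    seen_trans: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#!"):
                key, _, value = line[2:].partition("\t")
                metadata[key] = value
                continue
            if line == "#PLACES":
                section = "places"
                continue
            if line == "#TRANSITIONS":
                section = "transitions"
                continue
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            try:
                if section == "places":
                    if len(fields) != _PLACE_COLS:
                        raise ModelFormatError(
                            f"line {lineno}: expected {_PLACE_COLS} place columns, "
                            f"got {len(fields)}"
                        )
                    pid = fields[0]
                    if pid in seen_places:
                        raise ModelFormatError(f"line {lineno}: duplicate id {pid!r}")
                    seen_places.add(pid)
                    places.append(Place(
                        id=pid, label=fields[1], klass=fields[2],
                        entry_group=fields[3],
                        is_entry=_bool_field(fields[4], lineno),
                        is_output=_bool_field(fields[5], lineno),
                    ))
                elif section == "transitions":
                    if len(fields) != _TRANS_COLS:
                        raise ModelFormatError(
                            f"line {lineno}: expected {_TRANS_COLS} transition "
                            f"columns, got {len(fields)}"
                        )
                    tid = fields[0]
                    if tid in seen_trans:
                        raise ModelFormatError(f"line {lineno}: duplicate id {tid!r}")
                    seen_trans.add(tid)
                    inh = () if fields[2] == "-" else tuple(fields[2].split(","))
                    transitions.append(Transition(
                        id=tid,
                        activating_inputs=tuple(fields[1].split(",")),
                        inhibitory_inputs=inh,
                        outputs=tuple(fields[3].split(",")),
                    ))
                else:
                    raise ModelFormatError(
                        f"line {lineno}: content before #PLACES/#TRANSITIONS header"
                    )
            except ModelFormatError:
                raise
            except ValueError as exc:
                raise ModelFormatError(f"line {lineno}: {exc}") from exc
    if not places:
        raise ModelFormatError("no #PLACES section found")
    return PetriNetModel(places, transitions, metadata)


def read_interactions(path) -> list[InteractionRecord]:
    """Read an interaction-record table.

    Tab-separated columns: partner_a, partner_b ("-" if none), gate,
    dna_element ("-" if none), targets (comma-joined), evidence_count.
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ModelFormatError(
                    f"line {lineno}: expected 6 interaction columns, got {len(fields)}"
                )
            try:
                records.append(InteractionRecord(
                    partner_a=fields[0],
                    partner_b=None if fields[1] == "-" else fields[1],
                    gate=fields[2],
                    dna_element=None if fields[3] == "-" else fields[3],
                    targets=tuple(fields[4].split(",")),
                    evidence_count=int(fields[5]),
                ))
            except ValueError as exc:
                raise ModelFormatError(f"line {lineno}: {exc}") from exc
    return records


def write_interactions(records: list[InteractionRecord], path) -> None:
    lines = ["#partner_a\tpartner_b\tgate\tdna_element\ttargets\tevidence_count"]
    for r in records:
        lines.append("\t".join([
            r.partner_a, r.partner_b or "-", r.gate, r.dna_element or "-",
            ",".join(r.targets), str(r.evidence_count),
        ]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def export_graphml(model: PetriNetModel, path) -> None:
    """Export as GraphML: places and transitions as typed nodes, arcs as edges."""
    g = nx.DiGraph()
    for p in model.places:
        g.add_node(p.id, node_type="place", label=p.label, klass=p.klass,
                   entry_group=p.entry_group, is_entry=p.is_entry,
                   is_output=p.is_output)
    for t in model.transitions:
        g.add_node(t.id, node_type="transition")
        for pid in t.activating_inputs:
            g.add_edge(pid, t.id, kind="activating")
        for pid in t.inhibitory_inputs:
            g.add_edge(pid, t.id, kind="inhibitory")
        for pid in t.outputs:
            g.add_edge(t.id, pid, kind="activating")
    nx.write_graphml(g, path)
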