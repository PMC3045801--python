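"""Read and write workflow definitions as XPDL (WfMC) XML.

The supported element subset is XPDL 1.0: ``Package / WorkflowProcesses /
WorkflowProcess / Activities / Activity / Transitions / Transition`` plus
``ExtendedAttributes``.  Everything this engine adds on top of plain XPDL —
typed/constrained attribute specs, input/output artifact classes with
cardinalities, activity documentation, repeatability — is encoded as
``ExtendedAttribute`` elements (the standard XPDL escape hatch) whose names
carry the ``labflow.`` prefix and whose values are small JSON payloads:

======================  =====================================================
ExtendedAttribute name  Value payload
======================  =====================================================
``labflow.attribute``   ``{"name", "datatype", "required", "format",
                        "allowed", "range", "derivation", "doc"}``
``labflow.input``       ``{"artifact_type", "min", "max", "attributes": [...]}``
``labflow.output``      same shape as ``labflow.input``
``labflow.repeatable``  ``"true"`` / ``"false"``
``labflow.doc``         JSON list of free-text/URI references
======================  =====================================================

The order of ``ExtendedAttribute`` elements is significant and preserved: it
is the order of fields on the entry form.  Unknown elements and unknown
extended attributes are ignored with a logged warning, never an error —
documents written by other XPDL tools remain loadable.
"""

from __future__ import annotations

import io
import json
import logging
from pathlib import Path
from typing import BinaryIO, Union

from lxml import etree

from .workflow_model import (
    ActivitySpec,
    AttributeSpec,
    Direction,
    IOSpec,
    TransitionSpec,
    WorkflowDefinition,
    attribute_from_dict,
    attribute_to_dict,
    iospec_from_dict,
    iospec_to_dict,
)

__all__ = [
    "XPDL_NS",
    "EXT_PREFIX",
    "XpdlError",
    "XpdlParseError",
    "XpdlStructureError",
    "XpdlDefinitionError",
    "XpdlSerializeError",
    "parse_xpdl",
    "serialize_xpdl",
]

logger = logging.getLogger("labflow.xpdl")

XPDL_NS = "http://www.wfmc.org/2002/XPDL1.0"
EXT_PREFIX = "labflow."

Source = Union[str, Path, bytes, BinaryIO]


class XpdlError(ValueError):
    """Base class for XPDL reading/writing failures."""


class XpdlParseError(XpdlError):
    """The document is not well-formed XML."""


class XpdlStructureError(XpdlError):
    """Well-formed XML, but not a supported XPDL document."""


class XpdlDefinitionError(XpdlError):
    """An extension payload cannot be interpreted (names the activity/attribute)."""


class XpdlSerializeError(XpdlError):
    """The definition cannot be written (e.g. empty identifiers)."""


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _children(el: etree._Element, *names: str) -> list[etree._Element]:
    """Child elements with one of the given local names; warn about others."""
    wanted = []
    for child in el:
        if not isinstance(child.tag, str):  # comments, PIs
            continue
        if _local(child) in names:
            wanted.append(child)
    return wanted


_KNOWN = {
    "Package": {"PackageHeader", "RedefinableHeader", "WorkflowProcesses", "ExtendedAttributes"},
    "WorkflowProcess": {"ProcessHeader", "RedefinableHeader", "Activities", "Transitions", "ExtendedAttributes"},
    "Activity": {"ExtendedAttributes", "Description"},
}


def _warn_unknown(el: etree._Element, context: str) -> None:
    known = _KNOWN.get(context, set())
    for child in el:
        if isinstance(child.tag, str) and _local(child) not in known:
            logger.warning("ignoring unsupported XPDL element <%s> under <%s>", _local(child), context)


def _payload(value: str, where: str) -> object:
    try:
        return json.loads(value)
    except json.JSONDecodeError as exc:
        raise XpdlDefinitionError(f"{where}: extension payload is not valid JSON: {exc}") from None


def parse_xpdl(source: Source) -> WorkflowDefinition:
    """Load a workflow definition from an XPDL document.

    ``source`` may be a filesystem path, raw bytes, or a binary file object.
    Graph-level problems (dangling transitions, unreachable activities, …)
    are *not* raised here — run
    :func:`labflow.workflow_model.validate_definition` on the result to see
    them all at once; this function enforces only syntactic and typing rules.
    """
    parser = etree.XMLParser(remove_comments=False)
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source, parser)
        elif isinstance(source, (str, Path)):
            root = etree.parse(str(source), parser).getroot()
        else:
            root = etree.parse(source, parser).getroot()
    except etree.XMLSyntaxError as exc:
        raise XpdlParseError(f"malformed XML: {exc}") from None

    if _local(root) != "Package":
        raise XpdlStructureError(f"root element is <{_local(root)}>, expected <Package>")
    _warn_unknown(root, "Package")

    containers = _children(root, "WorkflowProcesses")
    processes = []
    for c in containers:
        processes.extend(_children(c, "WorkflowProcess"))
    if not processes:
        raise XpdlStructureError("document contains no <WorkflowProcess>")
    if len(processes) > 1:
        raise XpdlStructureError("multiple <WorkflowProcess> elements are not supported")
    proc = processes[0]
    _warn_unknown(proc, "WorkflowProcess")

    wf_id = proc.get("Id", "")
    wf_name = proc.get("Name", "")
    version = "1.0"
    for header in _children(proc, "RedefinableHeader"):
        for v in _children(header, "Version"):
            version = v.text or version

    activities: dict[str, ActivitySpec] = {}
    for acts in _children(proc, "Activities"):
        for act_el in _children(acts, "Activity"):
            act = _parse_activity(act_el)
            activities[act.id] = act

    transitions: list[TransitionSpec] = []
    for trans in _children(proc, "Transitions"):
        for t_el in _children(trans, "Transition"):
            transitions.append(
                TransitionSpec(
                    id=t_el.get("Id", ""),
                    from_activity=t_el.get("From", ""),
                    to_activity=t_el.get("To", ""),
                )
            )

    return WorkflowDefinition(
        id=wf_id, name=wf_name, version=version, activities=activities, transitions=tuple(transitions)
    )


def _parse_activity(act_el: etree._Element) -> ActivitySpec:
    act_id = act_el.get("Id", "")
    name = act_el.get("Name", "")
    _warn_unknown(act_el, "Activity")

    attributes: list[AttributeSpec] = []
    inputs: list[IOSpec] = []
    outputs: list[IOSpec] = []
    repeatable = True
    documentation: tuple[str, ...] = ()

    for ext_block in _children(act_el, "ExtendedAttributes"):
        for ext in _children(ext_block, "ExtendedAttribute"):
            ext_name = ext.get("Name", "")
            value = ext.get("Value")
            if value is None:
                value = ext.text or ""
            if not ext_name.startswith(EXT_PREFIX):
                logger.warning(
                    "activity %r: ignoring foreign extended attribute %r", act_id, ext_name
                )
                continue
            kind = ext_name[len(EXT_PREFIX):]
            where = f"activity {act_id!r}, extended attribute {ext_name!r}"
            if kind == "attribute":
                data = _payload(value, where)
                try:
                    attributes.append(attribute_from_dict(data))
                except (KeyError, ValueError, TypeError) as exc:
                    raise XpdlDefinitionError(
                        f"activity {act_id!r}, attribute "
                        f"{data.get('name', '?') if isinstance(data, dict) else '?'!r}: {exc}"
                    ) from None
            elif kind in ("input", "output"):
                data = _payload(value, where)
                direction = Direction.INPUT if kind == "input" else Direction.OUTPUT
                try:
                    spec = iospec_from_dict(data, direction)
                except (KeyError, ValueError, TypeError) as exc:
                    raise XpdlDefinitionError(f"{where}: {exc}") from None
                (inputs if kind == "input" else outputs).append(spec)
            elif kind == "repeatable":
                if value not in ("true", "false"):
                    raise XpdlDefinitionError(f"{where}: expected 'true' or 'false', got {value!r}")
                repeatable = value == "true"
            elif kind == "doc":
                data = _payload(value, where)
                if not isinstance(data, list) or not all(isinstance(s, str) for s in data):
                    raise XpdlDefinitionError(f"{where}: expected a JSON list of strings")
                documentation = tuple(data)
            else:
                logger.warning("activity %r: ignoring unknown extension %r", act_id, ext_name)

    return ActivitySpec(
        id=act_id,
        name=name,
        attributes=tuple(attributes),
        inputs=tuple(inputs),
        outputs=tuple(outputs),
        repeatable=repeatable,
        documentation=documentation,
    )


def serialize_xpdl(w: WorkflowDefinition) -> bytes:
    """Write a workflow definition as XPDL bytes (UTF-8, XML declaration).

    Round-trip contract: ``parse_xpdl(serialize_xpdl(w))`` is structurally
    equal to ``w`` on the supported subset, preserving attribute order.
    """
    _check_serializable(w)
    nsmap = {None: XPDL_NS}
    q = lambda tag: etree.QName(XPDL_NS, tag)  # noqa: E731

    pkg = etree.Element(q("Package"), Id=w.id, Name=w.name, nsmap=nsmap)
    header = etree.SubElement(pkg, q("PackageHeader"))
    etree.SubElement(header, q("XPDLVersion")).text = "1.0"
    etree.SubElement(header, q("Vendor")).text = "labflow"
    redef = etree.SubElement(pkg, q("RedefinableHeader"))
    etree.SubElement(redef, q("Version")).text = w.version

    procs = etree.SubElement(pkg, q("WorkflowProcesses"))
    proc = etree.SubElement(procs, q("WorkflowProcess"), Id=w.id, Name=w.name)
    proc_redef = etree.SubElement(proc, q("RedefinableHeader"))
    etree.SubElement(proc_redef, q("Version")).text = w.version

    acts = etree.SubElement(proc, q("Activities"))
    dumps = lambda obj: json.dumps(obj, ensure_ascii=False, sort_keys=True)  # noqa: E731
    for act in w.activities.values():
        act_el = etree.SubElement(acts, q("Activity"), Id=act.id, Name=act.name)
        ext_block = etree.SubElement(act_el, q("ExtendedAttributes"))

        def ext(name: str, value: str) -> None:
            etree.SubElement(
                ext_block, q("ExtendedAttribute"), Name=EXT_PREFIX + name, Value=value
            )

        for spec in act.attributes:
            ext("attribute", dumps(attribute_to_dict(spec)))
        for iospec in act.inputs:
            ext("input", dumps(iospec_to_dict(iospec)))
        for iospec in act.outputs:
            ext("output", dumps(iospec_to_dict(iospec)))
        if not act.repeatable:
            ext("repeatable", "false")
        if act.documentation:
            ext("doc", dumps(list(act.documentation)))

    trans_block = etree.SubElement(proc, q("Transitions"))
    for t in w.transitions:
        etree.SubElement(
            trans_block, q("Transition"), Id=t.id, From=t.from_activity, To=t.to_activity
        )

    buf = io.BytesIO()
    etree.ElementTree(pkg).write(buf, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return buf.getvalue()


def _check_serializable(w: WorkflowDefinition) -> None:
    if not w.id:
        raise XpdlSerializeError("workflow id must be non-empty")
    for act in w.activities.values():
        if not act.id:
            raise XpdlSerializeError("activity with empty id cannot be serialized")
        for spec in act.attributes:
            if not spec.name:
                raise XpdlSerializeError(
                    f"activity {act.id!r}: attribute with empty name cannot be serialized"
                )
        for iospec in act.inputs + act.outputs:
            if not iospec.artifact_type:
                raise XpdlSerializeError(
                    f"activity {act.id!r}: artifact type must be non-empty"
                )
            for spec in iospec.attributes:
                if not spec.name:
                    raise XpdlSerializeError(
                        f"activity {act.id!r}, artifact {iospec.artifact_type!r}: "
                        "attribute with empty name cannot be serialized"
                    )
    for t in w.transitions:
        if not t.id:
            raise XpdlSerializeError("transition with empty id cannot be serialized")
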