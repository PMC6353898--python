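"""End-to-end pipeline: structure -> contacts -> interface map -> designs.

`run_pipeline` drives every stage from a single config mapping and writes
deterministic text artifacts (TSV/JSON/FASTA plus a run log) to an output
directory.  Stage failures surface as PipelineError naming the stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .contacts import atomic_contacts, residue_contact_graph
from .design import (assemble_peptides, designs_to_fasta, designs_to_records,
                     make_knob_sites, order_knob_sites, reverse_control,
                     scramble_control)
from .fixtures import (build_ideal_helix, build_ideal_strand,
                       build_toy_complex, fixture_propensity_table)
from .propensity import PropensityTable
from .sockets import (enumerate_packing_cliques, identify_knob_sockets,
                      interface_filter, topology_map)
from .structure import Structure, assign_all_secondary_structure, parse_structure

DEFAULT_CONFIG = {
    "contact": {"cap_angstrom": 6.0, "mode": "voronoi"},
    "design": {"k_candidates": 3, "k_per_site": 3, "bridge_aa": "G",
               "max_designs": 24, "include_free": False, "controls": True},
    "propensity": {"source": "fixture", "pseudocount": 1.0},
    "seed": 0,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_input_structure(config: dict) -> Structure:
    inp = config.get("input", {})
    if "pdb" in inp:
        path = Path(inp["pdb"])
        if not path.exists():
            raise PipelineError("input", f"PDB file not found: {path}")
        return parse_structure(path.read_text(), source_id=path.stem)
    fixture = inp.get("fixture", "toy_complex")
    params = inp.get("params", {})
    if fixture == "toy_complex":
        return build_toy_complex(**params).structure
    if fixture == "ideal_helix":
        return build_ideal_helix(**params)
    if fixture == "ideal_strand":
        return build_ideal_strand(**params)
    raise PipelineError("input", f"unknown fixture kind {fixture!r}")


def load_propensity(config: dict) -> PropensityTable:
    prop = config.get("propensity", {})
    pseudo = float(prop.get("pseudocount", 1.0))
    if prop.get("tsv"):
        return PropensityTable.from_tsv(prop["tsv"], pseudocount=pseudo)
    return fixture_propensity_table(pseudocount=pseudo)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run all stages and write artifacts under ``outdir``.

    Returns a summary dict (socket/pair/design counts and file names).
    """
    config = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    structure = load_input_structure(config)

    target = set(config.get("target", ["A"]))
    partner = set(config.get("partner", ["B"]))
    unknown = (target | partner) - set(structure.chains)
    if unknown:
        raise PipelineError(
            "chains", f"unknown chain group member(s) {sorted(unknown)}; "
            f"structure has chains {sorted(structure.chains)}")

    try:
        assign_all_secondary_structure(structure)
    except Exception as exc:
        raise PipelineError("secondary_structure", str(exc)) from exc

    try:
        cap = float(config["contact"]["cap_angstrom"])
        mode = config["contact"]["mode"]
        contacts = atomic_contacts(structure, cap=cap, mode=mode)
        graph = residue_contact_graph(contacts)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("contacts", str(exc)) from exc
    pd.DataFrame(graph.to_records()).to_csv(outdir / "contacts.tsv", sep="\t", index=False)

    try:
        c3, c4 = enumerate_packing_cliques(graph)
        pairs, free = identify_knob_sockets(c3, c4, structure)
        interface = interface_filter(pairs, free, target, partner)
    except Exception as exc:
        raise PipelineError("sockets", str(exc)) from exc

    try:
        map_df = topology_map(interface)
    except ValueError as exc:
        raise PipelineError("map", str(exc)) from exc
    map_df.to_csv(outdir / "map.tsv", sep="\t", index=False)
    (outdir / "interface.json").write_text(interface_to_json(interface))

    try:
        table = load_propensity(config)
        table.to_tsv(outdir / "propensity.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("propensity", str(exc)) from exc

    dcfg = config["design"]
    try:
        sites = make_knob_sites(interface, structure, table,
                                k_candidates=int(dcfg["k_candidates"]),
                                include_free=bool(dcfg["include_free"]))
        if not sites:
            raise ValueError("no knob sites on the interface")
        ordered = order_knob_sites(sites)
        designs = assemble_peptides(ordered, table,
                                    k_per_site=int(dcfg["k_per_site"]),
                                    bridge_aa=dcfg["bridge_aa"],
                                    max_designs=int(dcfg["max_designs"]))
    except Exception as exc:
        raise PipelineError("design", str(exc)) from exc

    fasta = designs_to_fasta(designs)
    records = designs_to_records(designs)
    seed = int(config.get("seed", 0))
    if dcfg.get("controls") and designs:
        best = designs[0].sequence
        rows = []
        try:
            rows.append({"control": "scrambled", "of": "design01",
                         "sequence": scramble_control(best, seed=seed)})
        except ValueError:
            pass  # homopolymer top design has no distinct scramble
        rows.append({"control": "reversed", "of": "design01",
                     "sequence": reverse_control(best)})
        pd.DataFrame(rows).to_csv(outdir / "controls.tsv", sep="\t", index=False)
    (outdir / "designs.fasta").write_text(fasta)
    pd.DataFrame(records).to_csv(outdir / "designs.tsv", sep="\t", index=False)

    summary = {
        "version": __version__,
        "seed": seed,
        "structure": structure.source_id,
        "chains": {c: len(res) for c, res in structure.chains.items()},
        "n_atomic_contacts": len(contacts),
        "n_residue_edges": graph.graph.number_of_edges(),
        "n_cliques3": len(c3),
        "n_cliques4": len(c4),
        "n_filled_pairs": len(pairs),
        "n_interface_pairs": len(interface.pairs),
        "n_interface_free": len(interface.free_sockets),
        "n_designs": len(designs),
        "config": config,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "run.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log_lines = [
        f"ksdesign {__version__}",
        f"seed {seed}",
        f"input {structure.source_id}",
        f"parameters {json.dumps(config, sort_keys=True)}",
        f"interface pairs {len(interface.pairs)} free {len(interface.free_sockets)}",
        f"designs {len(designs)}",
    ]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def interface_to_json(interface) -> str:
    def ref(r):
        return {"chain": r.chain_id, "number": r.number, "icode": r.icode,
                "aa": r.aa, "ss": r.ss}

    payload = {
        "target_group": sorted(interface.target_group),
        "partner_group": sorted(interface.partner_group),
        "pairs": [
            {
                "socket": {"label": p.socket.label,
                           "ss_class": p.socket.ss_class,
                           "signature": [str(s) for s in p.socket.signature],
                           "x": ref(p.socket.x), "y": ref(p.socket.y),
                           "h": ref(p.socket.h)},
                "knob": ref(p.knob),
                "ambiguous": p.ambiguous,
            }
            for p in interface.pairs
        ],
        "free_sockets": [
            {"label": s.label, "ss_class": s.ss_class,
             "signature": [str(v) for v in s.signature],
             "x": ref(s.x), "y": ref(s.y), "h": ref(s.h)}
            for s in interface.free_sockets
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
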