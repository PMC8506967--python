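"""Join contacts, superposition deviations and conservation tiers.

The headline artifact is a per-contact-residue classification table: for
each domain residue touching the peptide it lists the contact kinds
(direct / water bridge), backbone-vs-sidechain side, the peptide residues
contacted, the conservation tier (universal / family / paralog / none), and
the post-superposition Calpha deviation against each comparison structure,
with identity-substitution flags. The orchestrating :func:`run_pipeline`
drives all three streams from one declarative YAML config and writes plain
CSV / text reports deterministically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import conservation as cons
from . import contacts as ct
from . import superpose as sp
from .errors import ConfigError, StageError
from .structure_io import Selection, load_structure

UNSCORED = "unscored"


def build_classification(
    contact_residues: Sequence[ct.ContactRecord],
    tiers: Optional[dict[int, str]],
    deviation_summaries: Optional[dict[str, dict]] = None,
    records: Optional[Sequence[ct.ContactRecord]] = None,
) -> pd.DataFrame:
    """One row per contact residue, joined across all analysis streams.

    ``contact_residues`` is the output of :func:`contacts.contact_residue_set`;
    ``tiers`` maps reference author numbers to conservation tiers (may be
    empty/None: residues are then flagged unscored, contacts kept intact);
    ``deviation_summaries`` maps comparison-structure ids to the output of
    :func:`superpose.contact_deviation_summary`.
    """
    tiers = tiers or {}
    deviation_summaries = deviation_summaries or {}
    bd_side = {}
    if records:
        for rec in records:
            key = rec.bd_residue.seq_num
            bd_side.setdefault(key, set()).add(rec.bd_side)
    rows = []
    for entry in contact_residues:
        res = entry.residue
        num = res.seq_num
        row = {
            "resnum": num,
            "resname": res.res_name,
            "chain": res.chain_id,
            "kinds": "+".join(sorted(entry.kinds)),
            "bd_side": "+".join(sorted(bd_side.get(num, set()))) or "unknown",
            "peptide_partners": ";".join(
                f"{p.res_name}{p.seq_num}" for p in entry.peptide_partners
            ),
            "tier": tiers.get(num, UNSCORED),
        }
        for name, summary in deviation_summaries.items():
            cd = summary["per_residue"].get(num)
            if cd is None or cd.deviation is None:
                row[f"dev_{name}"] = None
                row[f"subst_{name}"] = None
            else:
                row[f"dev_{name}"] = round(cd.deviation, 3)
                row[f"subst_{name}"] = not cd.identity_match
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("resnum", kind="stable").reset_index(drop=True)
    return df


def export_annotated_alignment(
    msa: cons.MSA,
    profile: cons.ConservationProfile,
    contact_resnums: Sequence[int],
    tiers: dict[int, str],
    reference_start: int = 1,
    block: int = 60,
) -> str:
    """Monospace rendering of the reference row with annotation lanes.

    Lanes: residue-number ruler, reference sequence, consensus (two-residue
    consensus rendered as ``x/y`` markers in a compact lane as the lowercase
    second residue), contact arrows (``^``), conservation tier tokens
    (U/F/P for universal/family/paralog, ``.`` for none).
    """
    mapping = msa.reference_column_numbers(reference_start)
    inv = {v: k for k, v in mapping.items()}
    contact_cols = {inv[n] for n in contact_resnums if n in inv}
    ref_row = msa.reference_row()
    n = msa.n_cols
    cons_lane = []
    pair_notes = []
    for col in profile.columns:
        if len(col.consensus) == 2:
            cons_lane.append(col.consensus[0])
            pair_notes.append(
                f"col {col.column_index}: consensus {col.consensus[0]}/{col.consensus[1]}"
            )
        elif len(col.consensus) == 1:
            cons_lane.append(col.consensus[0])
        else:
            cons_lane.append("-")
    tier_tok = {"universal": "U", "family": "F", "paralog": "P", "none": "."}
    tier_lane = []
    for j in range(n):
        resnum = mapping.get(j)
        tier_lane.append(tier_tok.get(tiers.get(resnum, "none"), ".") if resnum else " ")
    arrow_lane = ["^" if j in contact_cols else " " for j in range(n)]
    ruler = [" "] * n
    for j, resnum in mapping.items():
        if resnum % 10 == 0:
            label = str(resnum)
            if j + len(label) <= n:
                for k, ch in enumerate(label):
                    ruler[j + k] = ch
    out = []
    for start in range(0, n, block):
        end = min(n, start + block)
        out.append("ruler     " + "".join(ruler[start:end]))
        out.append("reference " + ref_row[start:end])
        out.append("consensus " + "".join(cons_lane[start:end]))
        out.append("contacts  " + "".join(arrow_lane[start:end]))
        out.append("tier      " + "".join(tier_lane[start:end]))
        out.append("")
    if pair_notes:
        out.append("two-residue consensus columns (X1/X2):")
        out.extend("  " + note for note in pair_notes)
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# pipeline orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        config = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config: {exc}") from exc
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key in ("reference", "output_dir"):
        if key not in config:
            raise ConfigError(f"config missing required key '{key}'")
    ref = config["reference"]
    for key in ("structure", "bd_chain", "peptide_chain"):
        if key not in ref:
            raise ConfigError(f"config reference block missing '{key}'")
    return config


def _selection(block: dict, chain_key: str, range_key: str) -> Selection:
    rng = block.get(range_key)
    if rng:
        return Selection(block[chain_key], int(rng[0]), int(rng[1]))
    return Selection(block[chain_key])


def run_pipeline(config: dict, base_dir: Optional[Path] = None) -> dict:
    """Run contacts -> superpositions -> conservation -> classification.

    Returns a manifest of output paths; outputs are deterministic for fixed
    inputs. Any stage failure raises :class:`StageError` after removing
    partial outputs.
    """
    base = Path(base_dir) if base_dir else Path.cwd()
    out_dir = base / config["output_dir"]
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def _log(stage: str, **kv):
        payload = json.dumps(kv, sort_keys=True, default=str)
        log_lines.append(f"[{stage}] {payload}")

    def _fail(stage: str, exc: Exception):
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, str(exc)) from exc

    # --- stage: load structures -------------------------------------------
    try:
        ref_block = config["reference"]
        ref_path = base / ref_block["structure"]
        ref_struct = load_structure(ref_path)
        bd_sel = _selection(ref_block, "bd_chain", "bd_range")
        pep_sel = _selection(ref_block, "peptide_chain", "peptide_range")
        comparisons = []
        for comp in config.get("comparisons", []):
            cpath = base / comp["structure"]
            comparisons.append(
                (comp["id"], load_structure(cpath), Selection(comp.get("chain", "A")), cpath)
            )
        _log("load", reference=str(ref_path), checksum=_sha256(ref_path),
             comparisons=[c[0] for c in comparisons])
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail("load", exc)

    # --- stage: contacts ---------------------------------------------------
    try:
        cparams = ct.ContactParams(**config.get("params", {}).get("contacts", {}))
        direct = ct.find_direct_contacts(ref_struct, bd_sel, pep_sel, cparams)
        bridges = ct.find_water_bridges(ref_struct, bd_sel, pep_sel, cparams)
        contact_set = ct.contact_residue_set(direct, bridges)
        contact_nums = [e.residue.seq_num for e in contact_set]
        _log("contacts", n_direct=len(direct), n_bridges=len(bridges),
             n_contact_residues=len(contact_set),
             direct_cutoff=cparams.direct_cutoff, hbond_cutoff=cparams.hbond_cutoff)
    except Exception as exc:
        _fail("contacts", exc)

    # --- stage: superpositions --------------------------------------------
    dev_summaries: dict[str, dict] = {}
    try:
        sparams = sp.SuperposeParams(**config.get("params", {}).get("superpose", {}))
        for name, mobile, msel, cpath in comparisons:
            result = sp.superpose_structures(ref_struct, mobile, bd_sel, msel, sparams)
            dev_summaries[name] = sp.contact_deviation_summary(result, contact_nums)
            prof = pd.DataFrame(
                [
                    {
                        "ref_resnum": p.ref_resnum,
                        "ref_resname": p.ref_resname,
                        "mobile_resnum": p.mobile_resnum,
                        "mobile_resname": p.mobile_resname,
                        "deviation_A": round(p.deviation, 4),
                        "retained": p.retained,
                        "identity_match": p.identity_match,
                    }
                    for p in result.deviation_profile
                ]
            )
            ppath = out_dir / f"profile_{name}.csv"
            prof.to_csv(ppath, index=False)
            written.append(ppath)
            _log("superpose", comparison=name, checksum=_sha256(cpath),
                 rmsd_retained=round(result.rmsd_retained, 4),
                 n_retained=result.n_retained, n_total=result.n_total,
                 prune_cutoff=sparams.prune_cutoff)
    except Exception as exc:
        _fail("superpose", exc)

    # --- stage: conservation ----------------------------------------------
    tiers: dict[int, str] = {}
    msa_block = config.get("msa") or {}
    annotated = None
    try:
        if msa_block:
            kparams = cons.ConservationParams(
                **config.get("params", {}).get("conservation", {})
            )
            ref_id = msa_block.get("reference_id", "reference")
            ref_start = int(msa_block.get("reference_start", 1))
            target_n = msa_block.get("subsample")

            def _profile(path):
                msa = cons.read_msa(base / path, reference_id=ref_id)
                if target_n and msa.n_rows > target_n:
                    msa = cons.maxmin_subsample(msa, target_n)
                return msa, cons.conservation_profile(msa, kparams)

            paralog_profiles = {}
            paralog_msa = None
            for name, path in (msa_block.get("paralog") or {}).items():
                paralog_msa, prof = _profile(path)
                paralog_profiles[name] = prof
            family_profile = universal_profile = None
            if msa_block.get("family"):
                _, family_profile = _profile(msa_block["family"])
            if msa_block.get("universal"):
                _, universal_profile = _profile(msa_block["universal"])
            if paralog_msa is not None:
                mapping = paralog_msa.reference_column_numbers(ref_start)
                tiers = cons.tier_columns(
                    paralog_profiles, family_profile, universal_profile, mapping
                )
                first_profile = next(iter(paralog_profiles.values()))
                annotated = export_annotated_alignment(
                    paralog_msa, first_profile, contact_nums, tiers, ref_start
                )
            _log("conservation", n_paralog_profiles=len(paralog_profiles),
                 threshold=kparams.similar_threshold, window=kparams.window)
        else:
            _log("conservation", skipped=True)
    except Exception as exc:
        _fail("conservation", exc)

    # --- stage: classification --------------------------------------------
    try:
        table = build_classification(
            contact_set, tiers, dev_summaries, records=list(direct) + list(bridges)
        )
        cpath_out = out_dir / "classification.csv"
        table.to_csv(cpath_out, index=False)
        written.append(cpath_out)
        if annotated is not None:
            apath = out_dir / "annotated_alignment.txt"
            apath.write_text(annotated)
            written.append(apath)
        _log("classify", n_rows=len(table))
    except Exception as exc:
        _fail("classify", exc)

    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    written.append(log_path)
    return {"output_dir": out_dir, "files": [str(p) for p in written]}
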