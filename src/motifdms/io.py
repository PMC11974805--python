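"""Plain-text serialization of motif configurations and variant tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .motif import MotifSpec, Window, enumerate_variant_space


def save_motif_config(spec: MotifSpec, path) -> None:
    """Write a motif as a plain key = value config file."""
    lines = [
        f"protein_name = {spec.protein_name}",
        f"first_residue = {spec.first_residue}",
        f"aa_sequence = {spec.aa_sequence}",
        f"dna_reference = {spec.dna_reference}",
        f"upstream_flank = {spec.upstream_flank}",
        f"downstream_flank = {spec.downstream_flank}",
        "windows = " + ";".join(f"{w.index},{w.codon_start},{w.n_codons}" for w in spec.windows),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_motif_config(path) -> MotifSpec:
    fields: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    windows = ()
    if fields.get("windows"):
        windows = tuple(
            Window(*(int(x) for x in item.split(",")))
            for item in fields["windows"].split(";")
        )
    return MotifSpec(
        protein_name=fields["protein_name"],
        first_residue=int(fields["first_residue"]),
        aa_sequence=fields["aa_sequence"],
        dna_reference=fields["dna_reference"],
        upstream_flank=fields["upstream_flank"],
        downstream_flank=fields["downstream_flank"],
        windows=windows,
    )


def variant_table(spec: MotifSpec, include_wildtype_aa: bool = True) -> pd.DataFrame:
    """Designed variant space: position, amino acid, window index."""
    window_of = {}
    for w in spec.windows:
        for i in range(w.n_codons):
            window_of[spec.window_first_residue(w) + i] = w.index
    rows = [
        {"position": pos, "amino_acid": aa, "window_index": window_of[pos]}
        for pos, aa in sorted(enumerate_variant_space(spec, include_wildtype_aa))
    ]
    return pd.DataFrame(rows)


def primer_layouts(spec: MotifSpec) -> pd.DataFrame:
    """Degenerate-primer layout per window: flank + N-stretch + flank."""
    rows = []
    for w in spec.windows:
        up, down = spec.window_flanks(w)
        rows.append(
            {
                "window_index": w.index,
                "first_residue": spec.window_first_residue(w),
                "n_codons": w.n_codons,
                "layout": up + "N" * w.nt_length + down,
            }
        )
    return pd.DataFrame(rows)
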