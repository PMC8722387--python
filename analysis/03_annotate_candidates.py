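#!/usr/bin/env python
"""Annotate the surviving candidates and score conservation of the hit
residue across a synthetic orthologue panel.

Real orthologue alignments require database sequences, so this driver
builds a synthetic panel: the candidate transcript's own protein plus five
'species' copies mutated at ~10% of residues *except* the candidate codon,
emulating a residue that evolution has kept fixed. The conservation score
of the candidate residue is then contrasted with the alignment-wide
average. Writes the consequence table under results/analysis/annotate/.
"""

import argparse
from pathlib import Path

import numpy as np

from poolscreen import consequence, variant_io
from poolscreen.screen_cascade import alt_fraction


class _Rec:
    def __init__(self, rid, seq):
        self.id, self.seq = rid, seq


def synthetic_orthologue_panel(protein, keep_residue, rng, n_species=5, rate=0.1):
    """Synthetic aligned orthologues (no gaps): reference plus mutated copies."""
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = [_Rec("candidate_species", protein)]
    for i in range(n_species):
        residues = list(protein)
        for j in range(len(residues)):
            if j == keep_residue - 1:
                continue
            if rng.random() < rate:
                residues[j] = str(rng.choice(alphabet))
        records.append(_Rec(f"orthologue_{i + 1}", "".join(residues)))
    return records


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/analysis/sim"))
    parser.add_argument("--screen", type=Path,
                        default=Path("results/analysis/screen"))
    parser.add_argument("--out", type=Path, default=Path("results/analysis/annotate"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    variants = variant_io.read_variant_table(args.sim / "variants.tsv")
    transcripts = variant_io.read_transcripts(
        args.sim / "transcripts.fa", args.sim / "cds.tsv"
    )
    candidate_ids = {
        line.split("\t")[0]
        for line in (args.screen / "candidates.tsv").read_text().splitlines()[1:]
    }
    candidates = [v for v in variants if v.variant_id in candidate_ids]
    calls = consequence.annotate_variants(candidates, transcripts)
    conservation = {}
    for v in candidates:
        call = calls[v.variant_id]
        if call.codon_index is None:
            continue
        transcript = transcripts[v.transcript_id]
        protein = "".join(
            consequence.translate_codon(transcript.cds[i : i + 3])
            for i in range(0, len(transcript.cds) - 3, 3)
        )
        panel = synthetic_orthologue_panel(protein, call.codon_index, rng)
        column = consequence.conservation_at(panel, "candidate_species",
                                             call.codon_index)
        conservation[v.variant_id] = column.conserved_fraction
        print(f"{v.variant_id}: {call.ref_aa}{call.codon_index}{call.alt_aa} "
              f"({call.consequence_class}), alt fraction "
              f"MUT={alt_fraction(v.counts['MUT']):.2f} "
              f"SIB={alt_fraction(v.counts['SIB']):.2f} "
              f"WT={alt_fraction(v.counts['WT']):.2f}; "
              f"residue conserved in {column.conserved_fraction:.0%} of the "
              f"synthetic orthologue panel")

    consequence.write_consequence_table(calls, args.out / "consequences.tsv",
                                        conservation=conservation)
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    main()
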