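"""Encode protein sequences into the four descriptor blocks.

Builds a two-record dataset, encodes it under each scheme, and prints the
block sizes plus the non-zero g-gap entries of a tiny sequence.  The g-gap
dipeptide composition (GGDC) counts ordered residue pairs separated by g=2
intervening residues; PseAAC adds lag-correlations of 10 physicochemical
property scales; GTPC and CTD summarize grouped tripeptides and class
compositions.
"""
import phagehydro as ph

dataset = ph.Dataset(
    [
        ph.ProteinRecord("lysin_like", "MKLTAEQAEARKAALKKLGLDEAAKAAGIKLSDLAAKAGLSKAALK"),
        ph.ProteinRecord("capsid_like", "MSTNPFGQQWVFYTPNNQSTVPQQGWQQFGNPQTGQFNPFTQQG"),
    ]
)

for scheme in ("ggdc+pseaac", "gtpc+ctd", "all"):
    matrix = ph.encode_combined(dataset, scheme=scheme)
    print(f"scheme {scheme:12s} -> {matrix.n_samples} samples x {matrix.n_features} features "
          f"(blocks: {', '.join(matrix.block_prefixes())})")

# the 2-gap pairs of ACDAC are A..A and C..C, each once among 2 positions
fv = ph.encode_ggdc("ACDAC", g=2)
nonzero = {n: round(v, 3) for n, v in zip(fv.names, fv.values) if v}
print(f"\nGGDC(g=2) of 'ACDAC': {nonzero}  (frequencies over L-g-1 = 2 gap pairs)")
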