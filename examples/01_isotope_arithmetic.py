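"""Isotope arithmetic basics: δ ↔ ratio ↔ atom-%, enrichment, recovery.

A labelled moss sample at δ¹⁵N = 735.74 ‰ against a reference at −6.19 ‰
illustrates the full chain from raw δ values to a tracer mass.
"""

import pulse15n as p

d_lab, d_ref = 735.74, -6.19

ratio = p.delta_to_ratio(d_lab)
atom_pct = p.delta_to_atom_percent(d_lab)
print(f"labelled moss: delta = {d_lab} permil -> 15N/14N = {ratio:.7f} "
      f"-> {atom_pct:.4f} atom-% 15N")

enr = p.enrichment(d_lab, d_ref)
print(f"enrichment over the unlabelled reference: {enr:.2f} permil")

# tracer mass in an 8.6 g N m-2 moss pool, labelled with 98 at.% tracer
ap_ref = p.delta_to_atom_percent(d_ref)
rec = p.recovery_mass(8.6, atom_pct, ap_ref, 98.0)
applied = p.applied_excess_15n(100.0, 98.0)  # 100 mg m-2 double-labelled NH4NO3
print(f"tracer recovered in the moss pool: {rec:.4f} g m-2 "
      f"= {p.relative_recovery(rec, applied):.1f}% of the {applied:.4f} g m-2 applied")
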