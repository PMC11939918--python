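"""Osmotic-stress design of the buffer system.

Vesicles are prepared in a hydration buffer (fixing their interior
osmolarity) and flowed in a dilution buffer (fixing the exterior).  A
hyperosmotic exterior pulls water out, deflates the adsorbed vesicles and
promotes rupture — the condition that turns a stubborn multicomponent
vesicle layer into a complete bilayer.
"""

from qcmdslb import BUFFERS, load_conditions_table, osmotic_condition

print("buffer osmolarities (ideal van't Hoff, mOsm):")
for name, buf in BUFFERS.items():
    solutes = " + ".join(f"{c:g} mM {s}" for s, c in buf.species)
    print(f"  {name}: {buf.osmolarity():6.1f}  ({solutes}, pH {buf.ph})")

print("\nosmotic condition during vesicle adsorption (hydration -> dilution):")
table = load_conditions_table()
for _, row in table.iterrows():
    res = osmotic_condition(BUFFERS[row["hydration_buffer"]],
                            BUFFERS[row["dilution_buffer"]])
    print(f"  run {row['figure']:>4}: {res.label.value:13s} "
          f"delta = {res.delta_mosm:+7.1f} mOsm "
          f"(NaCl-equivalent {res.nacl_equivalent_mm:+6.1f} mM)")

print("\nOnly the runs with a hyperosmotic dilution step (11A/11C/11D/12A) "
      "formed complete bilayers; isosmotic adsorption left vesicles intact "
      "or only partially ruptured.")
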