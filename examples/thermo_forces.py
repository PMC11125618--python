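"""Van't Hoff thermodynamics and binding-force diagnosis from Ka(T).

Takes apparent binding constants at three temperatures (rising with T, as
for an entropy-driven binder), extracts dH and dS from the van't Hoff line,
evaluates dG at each temperature, and classifies the dominant force from
the sign pattern. Also computes ligand efficiency for a docking energy.
"""

from specbind.thermo import LigandRecord, gibbs_from_Ka, vant_hoff_analysis

ka_by_T = {293.0: 1.5e6, 298.0: 2.0e6, 303.0: 2.6e6}
result = vant_hoff_analysis(ka_by_T)

print(f"dH = {result.delta_H_kJ:+.2f} kJ/mol,  dS = {result.delta_S_J:+.2f} J/(mol K)")
for t, dg in sorted(result.delta_G_kJ_by_T.items()):
    print(f"  dG({t:.0f} K) = {dg:+.2f} kJ/mol   (from dG = dH - T dS; "
          f"-RT ln Ka gives {gibbs_from_Ka(ka_by_T[t], t):+.2f})")
print(f"force class: {result.force_class.value}  (dH > 0 and dS > 0 => hydrophobic driving force)")

pfbs = LigandRecord(name="PFBS", formula="C4F9O3S", binding_energy_kcal=-5.196)
print(f"\n{pfbs.name}: {pfbs.n_heavy} heavy atoms, LE = {pfbs.LE:.3f} kcal/mol per heavy atom")
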