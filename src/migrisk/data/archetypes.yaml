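# Product archetype geometries (synthetic representative defaults).
#
# Two archetypes span the mouthing-product space: a pacifier for products
# meant to be mouthed long-term, a doll for products mouthed occasionally.
# a_contact_cm2 = 10 is the typical child mouthing area; d_p is the wall /
# limb thickness engaged in one-sided diffusion; v_f is the saliva volume
# in contact. Values are representative defaults, fully overridable.
archetypes:
  pacifier:
    material_default: silicone
    d_p_cm: 0.30
    v_p_cm3: 5.0
    v_f_cm3: 5.0
    a_contact_cm2: 10.0
  doll:
    material_default: PVC
    d_p_cm: 0.20
    v_p_cm3: 50.0
    v_f_cm3: 5.0
    a_contact_cm2: 10.0
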