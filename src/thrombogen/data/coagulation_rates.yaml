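# TF-initiated extrinsic coagulation cascade: reaction inventory, rate
# constants and mean plasma concentrations after Hockin, Jones, Everse &
# Mann, "A model for the stoichiometric regulation of blood coagulation",
# J Biol Chem 277(21):18322-18333 (2002), Tables 1-2.
#
# Units: unimolecular rate constants 1/s, bimolecular 1/(M*s);
# concentrations mol/L. Complex species are written with "=" joiners
# (e.g. TF=VIIa is the tissue factor / factor VIIa complex).
#
# Every constant below is editable; the simulator takes whatever inventory
# this file defines and never hard-codes counts.

mean_plasma:            # Hockin 2002 Table 1 physiologic initial conditions
  VII:   1.0e-8         # zymogen factor VII
  VIIa:  1.0e-10        # trace circulating activated VII
  X:     1.6e-7
  IX:    9.0e-8
  II:    1.4e-6         # prothrombin
  VIII:  7.0e-10
  V:     2.0e-8
  TFPI:  2.5e-9
  ATIII: 3.4e-6

reactions:
  # -- TF / VII(a) assembly ------------------------------------------------
  - {name: tf_vii_on,        reactants: [TF, VII],            products: [TF=VII],                 k: 3.2e+6}   # k2
  - {name: tf_vii_off,       reactants: [TF=VII],             products: [TF, VII],                k: 3.1e-3}   # k1
  - {name: tf_viia_on,       reactants: [TF, VIIa],           products: [TF=VIIa],                k: 2.3e+7}   # k4
  - {name: tf_viia_off,      reactants: [TF=VIIa],            products: [TF, VIIa],               k: 3.1e-3}   # k3
  - {name: viia_tf_act_vii,  reactants: [TF=VIIa, VII],       products: [TF=VIIa, VIIa],          k: 4.4e+5}   # k5
  - {name: xa_act_vii,       reactants: [Xa, VII],            products: [Xa, VIIa],               k: 1.3e+7}   # k6
  - {name: iia_act_vii,      reactants: [IIa, VII],           products: [IIa, VIIa],              k: 2.3e+4}   # k7
  # -- extrinsic tenase on X and IX ----------------------------------------
  - {name: tf_viia_x_on,     reactants: [TF=VIIa, X],         products: [TF=VIIa=X],              k: 2.5e+7}   # k9
  - {name: tf_viia_x_off,    reactants: [TF=VIIa=X],          products: [TF=VIIa, X],             k: 1.05}     # k8
  - {name: tf_viia_x_cat,    reactants: [TF=VIIa=X],          products: [TF=VIIa=Xa],             k: 6.0}      # k10
  - {name: tf_viia_xa_on,    reactants: [TF=VIIa, Xa],        products: [TF=VIIa=Xa],             k: 2.2e+7}   # k12
  - {name: tf_viia_xa_off,   reactants: [TF=VIIa=Xa],         products: [TF=VIIa, Xa],            k: 19.0}     # k11
  - {name: tf_viia_ix_on,    reactants: [TF=VIIa, IX],        products: [TF=VIIa=IX],             k: 1.0e+7}   # k14
  - {name: tf_viia_ix_off,   reactants: [TF=VIIa=IX],         products: [TF=VIIa, IX],            k: 2.4}      # k13
  - {name: tf_viia_ix_cat,   reactants: [TF=VIIa=IX],         products: [TF=VIIa, IXa],           k: 1.8}      # k15
  # -- fluid-phase activation ----------------------------------------------
  - {name: xa_act_ii,        reactants: [Xa, II],             products: [Xa, IIa],                k: 7.5e+3}   # k16
  - {name: iia_act_viii,     reactants: [IIa, VIII],          products: [IIa, VIIIa],             k: 2.0e+7}   # k17
  - {name: iia_act_v,        reactants: [IIa, V],             products: [IIa, Va],                k: 2.0e+7}   # k26
  # -- intrinsic tenase -----------------------------------------------------
  - {name: tenase_on,        reactants: [VIIIa, IXa],         products: [IXa=VIIIa],              k: 1.0e+7}   # k19
  - {name: tenase_off,       reactants: [IXa=VIIIa],          products: [VIIIa, IXa],             k: 5.0e-3}   # k18
  - {name: tenase_x_on,      reactants: [IXa=VIIIa, X],       products: [IXa=VIIIa=X],            k: 1.0e+8}   # k21
  - {name: tenase_x_off,     reactants: [IXa=VIIIa=X],        products: [IXa=VIIIa, X],           k: 1.0e-3}   # k20
  - {name: tenase_x_cat,     reactants: [IXa=VIIIa=X],        products: [IXa=VIIIa, Xa],          k: 8.2}      # k22
  # -- VIIIa A2-domain dissociation (spontaneous tenase decay) --------------
  - {name: viiia_decay,      reactants: [VIIIa],              products: [VIIIa1-L, VIIIa2],       k: 6.0e-3}   # k24
  - {name: viiia_reform,     reactants: [VIIIa1-L, VIIIa2],   products: [VIIIa],                  k: 2.2e+4}   # k23
  - {name: tenase_x_decay,   reactants: [IXa=VIIIa=X],        products: [VIIIa1-L, VIIIa2, X, IXa], k: 1.0e-3} # k25
  - {name: tenase_decay,     reactants: [IXa=VIIIa],          products: [VIIIa1-L, VIIIa2, IXa],  k: 1.0e-3}   # k25
  # -- prothrombinase -------------------------------------------------------
  - {name: prothrombinase_on,  reactants: [Xa, Va],           products: [Xa=Va],                  k: 4.0e+8}   # k28
  - {name: prothrombinase_off, reactants: [Xa=Va],            products: [Xa, Va],                 k: 0.2}      # k27
  - {name: ptase_ii_on,      reactants: [Xa=Va, II],          products: [Xa=Va=II],               k: 1.0e+8}   # k30
  - {name: ptase_ii_off,     reactants: [Xa=Va=II],           products: [Xa=Va, II],              k: 103.0}    # k29
  - {name: ptase_ii_cat,     reactants: [Xa=Va=II],           products: [Xa=Va, mIIa],            k: 63.5}     # k31
  - {name: miia_to_iia,      reactants: [mIIa, Xa=Va],        products: [IIa, Xa=Va],             k: 1.5e+7}   # k32
  # -- TFPI inhibition ------------------------------------------------------
  - {name: tfpi_xa_on,       reactants: [Xa, TFPI],           products: [Xa=TFPI],                k: 9.0e+5}   # k34
  - {name: tfpi_xa_off,      reactants: [Xa=TFPI],            products: [Xa, TFPI],               k: 3.6e-4}   # k33
  - {name: tfpi_quat_on,     reactants: [TF=VIIa=Xa, TFPI],   products: [TF=VIIa=Xa=TFPI],        k: 3.2e+8}   # k36
  - {name: tfpi_quat_off,    reactants: [TF=VIIa=Xa=TFPI],    products: [TF=VIIa=Xa, TFPI],       k: 1.1e-4}   # k35
  - {name: tfpi_xa_tf_viia,  reactants: [TF=VIIa, Xa=TFPI],   products: [TF=VIIa=Xa=TFPI],        k: 5.0e+7}   # k37
  # -- ATIII (irreversible serpin) inhibition -------------------------------
  - {name: atiii_xa,         reactants: [Xa, ATIII],          products: [Xa=ATIII],               k: 1.5e+3}   # k38
  - {name: atiii_miia,       reactants: [mIIa, ATIII],        products: [mIIa=ATIII],             k: 7.1e+3}   # k39
  - {name: atiii_ixa,        reactants: [IXa, ATIII],         products: [IXa=ATIII],              k: 4.9e+2}   # k40
  - {name: atiii_iia,        reactants: [IIa, ATIII],         products: [IIa=ATIII],              k: 7.1e+3}   # k41
  - {name: atiii_tf_viia,    reactants: [TF=VIIa, ATIII],     products: [TF=VIIa=ATIII],          k: 2.3e+2}   # k42
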