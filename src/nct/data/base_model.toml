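# Reconstructed base parameterization of the karyopherin transport model.
# Compartment volumes in fL, concentrations in µM, bimolecular rate constants
# in 1/(µM·s), unimolecular in 1/s.  Species concentrations are placed in the
# listed home compartment at t = 0.  Values are order-of-magnitude defaults
# drawn from the published import/export model literature; every entry can be
# overridden from a user configuration file.

[compartments]
cytoplasm = 1200.0
nucleus = 500.0
pore = 10.0

[species]
Ran = { conc = 25.0, compartment = "cytoplasm" }     # loaded as RanGDP
NTF2 = { conc = 16.0, compartment = "cytoplasm" }
RCC1 = { conc = 0.7, compartment = "nucleus" }
RanGAP = { conc = 1.0, compartment = "cytoplasm" }
RanBP1 = { conc = 4.0, compartment = "cytoplasm" }
RanBP3 = { conc = 0.05, compartment = "nucleus" }
ImpA = { conc = 3.0, compartment = "cytoplasm" }
ImpB = { conc = 1.0, compartment = "cytoplasm" }
CAS = { conc = 3.0, compartment = "cytoplasm" }
CRM1 = { conc = 0.8, compartment = "cytoplasm" }

[rates]
kon_impab = 1.0            # ImpA + ImpB association
koff_impab = 0.05
kon_ntf2_rangdp = 1.0
koff_ntf2_rangdp = 2.0
kon_ranbp1_rangtp = 1.0
koff_ranbp1_rangtp = 0.005
kon_rcc1_rangdp = 10.0
koff_rcc1_rangdp = 1.0
kcat_rcc1 = 10.0           # nucleotide exchange turnover
kcat_rangap = 10.0         # RanBP1:RanGTP hydrolysis, RanGAP-catalyzed
k_rangap_basal = 0.1       # unstimulated hydrolysis of free RanGTP
k_rangtp_impb = 10.0        # RanGTP-driven release of ImpB from import complexes
kon_impb_rangtp = 10.0
koff_impb_rangtp = 0.005
k_ranbp1_strip = 2.0       # RanBP1 removal of RanGTP from carrier complexes
kon_cas_rangtp = 2.0
koff_cas_rangtp = 2.0
kon_casrangtp_impa = 10.0
koff_casrangtp_impa = 0.02
kon_cas_impa = 1.0         # RanGTP-independent CAS:ImpA competition
koff_cas_impa = 0.01
k_rangtp_casimpa = 5.0     # RanGTP loading onto pre-formed CAS:ImpA
kon_crm1_ranbp3 = 1.0
koff_crm1_ranbp3 = 0.1
kon_crm1ranbp3_rangtp = 1.0
koff_crm1ranbp3_rangtp = 0.1
kon_crm1_rangtp = 1.0
koff_crm1_rangtp = 2.0
k_trans = 1.0              # pore translocation step at the reference pore count
k_trans_cargo = 1.0        # transit of cargo-laden carrier complexes
k_trans_ranbp3 = 0.05      # slow shuttling of free RanBP3
k_trans_impa = 0.1         # slow CAS-independent shuttling of free importin-alpha
kon_cargo = 0.1            # default cargo-carrier association (association-limited loading)
kon_cargo_export = 0.1
k_passive_cargo = 0.005    # slow passive pore permeation of free cargo

[pores]
reference_count = 2770

[[pores.classes]]
count = 2770
selectivity = "all"
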