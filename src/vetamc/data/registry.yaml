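# Default active-ingredient registry for the Fiji 2017-2021 veterinary
# antimicrobial import analysis.
#
# Importance categories follow the WOAH (OIE) list of antimicrobial agents of
# veterinary importance and the WHO list of critically important antimicrobials
# for human medicine, encoded exactly as applied in the study summary tables.
# Categories:
#   woah: VCIA | VHIA | VIA | UNCLASSIFIED
#   who:  CIA_HIGHEST | CIA_HIGH | HIGHLY_IMPORTANT | IMPORTANT | UNCLASSIFIED
#
# iu_to_mg is the mass-equivalence factor for potency-labelled (IU) products,
# in mg per IU.  The benzylpenicillin standard is 1 mg = 1667 IU, i.e. 0.0006
# mg/IU.
list_edition:
  woah: "WOAH list of antimicrobial agents of veterinary importance, 2021 edition"
  who: "WHO critically important antimicrobials for human medicine, 6th revision"

ingredients:
  - name: gentamicin
    synonyms: [gentamycin, gentamycin sulphate, gentamicin sulphate, gentamicin sulfate]
    class: aminoglycosides
    woah: VCIA
    who: CIA_HIGH

  - name: cephalothin
    synonyms: [cephalothin sodium, cefalotin, cefalotin sodium]
    class: cephalosporins
    subclass: first-generation cephalosporin
    woah: VHIA
    who: HIGHLY_IMPORTANT

  - name: cephazolin
    synonyms: [cephazolin sodium, cefazolin, cefazolin sodium]
    class: cephalosporins
    subclass: first-generation cephalosporin
    woah: VHIA
    who: HIGHLY_IMPORTANT

  - name: cefuroxime
    synonyms: [cefuroxime sodium]
    class: cephalosporins
    subclass: second-generation cephalosporin
    woah: VHIA
    who: HIGHLY_IMPORTANT

  - name: ciprofloxacin
    synonyms: [ciprofloxacin hydrochloride]
    class: quinolones
    subclass: fluoroquinolone
    woah: VCIA
    who: CIA_HIGHEST

  - name: norfloxacin
    synonyms: []
    class: quinolones
    subclass: fluoroquinolone
    woah: VCIA
    who: CIA_HIGHEST

  - name: lincomycin
    synonyms: [lincomycin hydrochloride, lincomycin hydrochloride monohydrate]
    class: lincosamides
    woah: VHIA
    who: HIGHLY_IMPORTANT

  - name: erythromycin
    synonyms: []
    class: macrolides
    woah: VCIA
    who: CIA_HIGHEST

  - name: penicillin
    synonyms: [penicillin g, penicillin g procaine, procaine penicillin,
               benzylpenicillin, penicillin g sodium, penicillin g potassium]
    class: penicillins
    woah: VCIA
    who: CIA_HIGH
    iu_to_mg: 0.0006

  - name: sulfadiazine
    synonyms: [silver sulfadiazine, sulphadiazine]
    class: sulfonamides
    woah: VCIA
    who: HIGHLY_IMPORTANT

  - name: sulfamethoxazole
    synonyms: [sulphamethoxazole]
    class: sulfonamides
    woah: VCIA
    who: HIGHLY_IMPORTANT

  - name: tetracycline
    synonyms: [tetracycline hydrochloride]
    class: tetracyclines
    woah: VCIA
    who: HIGHLY_IMPORTANT

  - name: metronidazole
    synonyms: []
    class: nitroimidazoles
    woah: UNCLASSIFIED
    who: IMPORTANT
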