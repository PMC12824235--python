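{
  "hydrogen": "[H][H]",
  "oxygen": "O=O",
  "nitrogen": "N#N",
  "chlorine": "ClCl",
  "fluorine": "FF",
  "water": "O",
  "hydrogen peroxide": "OO",
  "ammonia": "N",
  "hydrazine": "NN",
  "hydrogen chloride": "Cl",
  "hydrogen fluoride": "F",
  "hydrogen sulfide": "S",
  "carbon monoxide": "[C-]#[O+]",
  "carbon dioxide": "O=C=O",
  "methane": "C",
  "ethane": "CC",
  "propane": "CCC",
  "butane": "CCCC",
  "isobutane": "CC(C)C",
  "pentane": "CCCCC",
  "hexane": "CCCCCC",
  "ethylene": "C=C",
  "propene": "CC=C",
  "1-butene": "CCC=C",
  "1,3-butadiene": "C=CC=C",
  "acetylene": "C#C",
  "cyclopropane": "C1CC1",
  "cyclopentane": "C1CCCC1",
  "cyclohexane": "C1CCCCC1",
  "benzene": "c1ccccc1",
  "toluene": "Cc1ccccc1",
  "styrene": "C=Cc1ccccc1",
  "naphthalene": "c1ccc2ccccc2c1",
  "methanol": "CO",
  "ethanol": "CCO",
  "1-propanol": "CCCO",
  "2-propanol": "CC(C)O",
  "ethylene glycol": "OCCO",
  "glycerol": "OCC(O)CO",
  "dimethyl ether": "COC",
  "diethyl ether": "CCOCC",
  "formaldehyde": "C=O",
  "acetaldehyde": "CC=O",
  "acetone": "CC(C)=O",
  "formic acid": "OC=O",
  "acetic acid": "CC(=O)O",
  "methyl formate": "COC=O",
  "methylamine": "CN",
  "dimethylamine": "CNC",
  "trimethylamine": "CN(C)C",
  "ethylamine": "CCN",
  "aniline": "Nc1ccccc1",
  "phenol": "Oc1ccccc1",
  "pyridine": "c1ccncc1",
  "furan": "c1ccoc1",
  "thiophene": "c1ccsc1",
  "pyrrole": "c1cc[nH]c1",
  "acetonitrile": "CC#N",
  "hydrogen cyanide": "C#N",
  "methanethiol": "CS",
  "chloromethane": "CCl",
  "dichloromethane": "ClCCl",
  "chloroform": "ClC(Cl)Cl",
  "glycine": "NCC(=O)O",
  "urea": "NC(N)=O",
  "1-(2-methylphenyl)-3-(3-methylpyridin-2-yl)urea": "Cc1ccccc1NC(=O)Nc1ncccc1C"
}
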