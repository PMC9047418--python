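# Systematic IUPAC-IUB fatty acyl names: saturated/unsaturated acids,
# dioic acids, substituent prefixes (hydroxy, oxo, epoxy, hydroperoxy,
# carboxy, methoxy, alkyl branches), nor-modified prostane parents, and
# the N-acyl-ethanolamine pattern.  Multiplier stems are written without
# their final 'a' ("octadec"); the 'a' reappears morphologically before
# consonant infixes ("octadeca-9,12-dien...", "eicosatrien...").

iupac        = nae | fa ;
nae          = 'N-(' rac prefix_list core ')-ethanolamine' ;
rac          = '(±)-' | '(+/-)-' | '' ;
fa           = prefix_list core ;

prefix_list  = prefix prefix_list | '' ;
prefix       = nor_prefix | sub_prefix | loc_prefix ;
nor_prefix   = locants '-' cmult 'nor-' ;
sub_prefix   = locants '-' cmult_opt substname dash_opt ;
loc_prefix   = locants '-' ;
cmult        = 'di' | 'tri' | 'tetra' | 'penta' | 'hexa' ;
cmult_opt    = '' | cmult ;
dash_opt     = '-' | '' ;
substname    = 'hydroxy' | 'oxo' | 'epoxy' | 'hydroperoxy' | 'carboxy'
             | 'methoxy' | 'amino' | 'sulfanyl' | alkyl ;
alkyl        = mult 'yl' ;

core         = unsat_core | sat_core | prost_core ;
sat_core     = mult 'an' acid_end ;
unsat_core   = mult dblock kind acid_end ;
kind         = 'en' | 'yn' ;
dblock       = 'a-' locants '-' ncount_opt
             | '-' locants '-' ncount_opt
             | 'a' ncount
             | ncount_opt ;
ncount       = 'di' | 'tri' | 'tetra' | 'penta' | 'hexa' ;
ncount_opt   = ncount | '' ;
prost_core   = 'prostan' acid_end ;
acid_end     = 'oic acid' | 'oyl' | 'edioic acid'
             | '-' locants '-dioic acid' | 'dioic acid' ;

locants      = locant ',' locants | locant ;
locant       = number locant_stereo | number ;
locant_stereo = 'R' | 'S' | 'Z' | 'E' ;
number       = [0-9] number | [0-9] ;

mult         = 'heptapentacont' | 'heptatetracont' | 'pentapentacont'
             | 'pentatetracont' | 'tetrapentacont' | 'tetratetracont'
             | 'heptatriacont' | 'hexapentacont' | 'hexatetracont'
             | 'nonapentacont' | 'nonatetracont' | 'octapentacont'
             | 'octatetracont' | 'pentatriacont' | 'tetratriacont'
             | 'henpentacont' | 'hentetracont' | 'hexatriacont'
             | 'nonatriacont' | 'octatriacont' | 'tripentacont'
             | 'tritetracont' | 'dopentacont' | 'dotetracont'
             | 'hentriacont' | 'tritriacont' | 'dotriacont'
             | 'pentacont' | 'tetracont' | 'heneicos' | 'heptacos'
             | 'heptadec' | 'hexacont' | 'pentacos' | 'pentadec'
             | 'tetracos' | 'tetradec' | 'triacont' | 'henicos'
             | 'hexacos' | 'hexadec' | 'nonacos' | 'nonadec'
             | 'octacos' | 'octadec' | 'tricos' | 'tridec' | 'docos'
             | 'dodec' | 'eicos' | 'undec' | 'hept' | 'icos' | 'meth'
             | 'pent' | 'prop' | 'but' | 'dec' | 'eth' | 'hex' | 'non'
             | 'oct' ;
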