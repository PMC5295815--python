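pair,primer,sequence,fragment_length_bp,amplified_genera
Daer,DaerF,GATCAAATTTATAATAC,204,Daerlac
Daer,DaerR,TTCTGATTAATAAGG,204,Daerlac
Form,FormF,GATCAAACYTTTAAYTC,220,Camponotus;Myrmecia;Polyrhachis
Form,FormR,CCWGATCCTTCATTAATAAA,220,Camponotus;Myrmecia;Polyrhachis
Myrm,MyrmF,ATTAGCTTCTATTATTG,142,Myrmarachne
Myrm,MyrmR,TCTATAGAAATWCCTTCAG,142,Myrmarachne
Bothm,BothmF,TCCTCATGTTCAGGAATAATTAA,215,Bothriomutilla
Bothm,BothmR,ATTAAGAGCATAATGGATATTGGG,215,Bothriomutilla
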