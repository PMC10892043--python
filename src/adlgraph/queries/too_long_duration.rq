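PREFIX adl: <http://example.org/adl/ontology#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>

CONSTRUCT {
  ?problem a adl:TooLongDuration ;
           adl:isProblemOf ?patient ;
           adl:problem_date ?start ;
           adl:problem_rate ?duration .
}
WHERE {
  ?activity a adl:Activity ;
            adl:activity_pk ?activity_pk ;
            adl:activity_start ?start ;
            adl:activity_end ?end ;
            adl:activity_duration ?duration ;
            adl:activity_name ${activity_name} ;
            adl:refersToUser ?patient .
  FILTER( ?duration > ${duration_threshold} )
  BIND( IRI(CONCAT("${resource_base}problem/too-long-duration/",
                   ENCODE_FOR_URI(?activity_pk))) AS ?problem )
}
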